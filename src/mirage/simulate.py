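"""Seeded generators for every input the analysis consumes.

The simulator emulates the data structure of a cross-sectional brain-aging
transcriptomics study in a short-lived fish: five age groups with a fixed
number of animals each, an RPKM-like nonnegative expression matrix with
multiplicative log-normal noise, a miRNA whose mean expression rises
geometrically ~15-fold from the youngest to the oldest group, and a set of
target genes whose log-expression is repressed in proportion to the
standardized miRNA level. It also fabricates small RNA-seq reads (mature
sequence +/- 3' isomiR shift, followed by the sequencing adapter, with
substitution errors and Ns), differential-expression tables with a
controllable per-type composition, and 3'-UTR sequences with planted seed
sites.

All randomness flows from a single :class:`numpy.random.Generator` seeded
by ``SimulationConfig.rng_seed``; draw order is fixed, so identical
configurations give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import DEFAULT_ADAPTER, MatureReference, Read
from .errors import ConfigError, InputError
from .targets import SeedDefinition, scan_utr

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """All generative knobs, with the study's conditions as defaults.

    ``ages`` are in weeks; ``mirna_fold_change`` is the old/young ratio of
    mean miRNA expression; ``coupling`` is the repression strength in log2
    units per unit of standardized miRNA expression; ``noise_sigma`` is the
    standard deviation of the log-normal noise (natural-log scale);
    ``isomir_len_shift`` maps 3' length offsets (nt, may be positive) to
    probabilities.
    """

    ages: Sequence[float] = (3.0, 9.0, 15.0, 21.0, 27.0)
    n_per_age: int = 5
    n_genes: int = 2000
    n_targets: int = 200
    mirna_fold_change: float = 15.0
    coupling: float = 1.0
    noise_sigma: float = 0.3
    read_count: int = 2000
    error_rate: float = 0.001
    n_rate: float = 0.001
    adapter: str = DEFAULT_ADAPTER
    isomir_len_shift: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.70, -2: 0.05, -1: 0.10, 1: 0.10, 2: 0.05}
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_targets > self.n_genes:
            raise ConfigError(
                f"n_targets ({self.n_targets}) exceeds n_genes ({self.n_genes})"
            )
        if self.mirna_fold_change <= 0:
            raise ConfigError("mirna_fold_change must be > 0")
        for name in ("error_rate", "n_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {rate}")
        if len(self.ages) < 2:
            raise ConfigError("need at least two age groups")
        if self.n_per_age < 1 or self.n_genes < 1:
            raise ConfigError("n_per_age and n_genes must be positive")
        probs = np.array(list(self.isomir_len_shift.values()), dtype=float)
        if len(probs) == 0 or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ConfigError("isomir_len_shift must be a probability distribution")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass
class ExpressionMatrix:
    """Gene x sample nonnegative expression plus per-sample metadata.

    ``values``: DataFrame indexed by gene id, columns = sample ids.
    ``samples``: DataFrame indexed by sample id with ``age_weeks`` and
    ``replicate`` columns, in the same column order as ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise InputError("expression columns and sample sheet disagree")

    def age_means(self) -> tuple[pd.DataFrame, pd.Series]:
        """Collapse replicates: per-age mean expression and age vector."""
        groups = self.samples["age_weeks"]
        means = self.values.T.groupby(groups).mean().T
        return means, pd.Series(means.columns, index=means.columns)


@dataclass
class GroundTruth:
    """What the generator actually planted, keyed by emitted identifiers."""

    target_gene_ids: frozenset = frozenset()
    read_sources: dict[str, str] = field(default_factory=dict)
    gene_types: dict[str, int] = field(default_factory=dict)
    planted_sites: dict[str, list[tuple[int, str]]] = field(default_factory=dict)


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.Series, GroundTruth]:
    """Expression matrix, miRNA per-sample vector and planted target set.

    The miRNA mean interpolates geometrically between the youngest and
    oldest groups so the old/young ratio equals ``mirna_fold_change``
    exactly when ``noise_sigma`` is 0. Target genes receive the term
    ``-coupling * z`` on the log2 scale, where ``z`` is the standardized
    per-sample log2 miRNA level; non-targets are independent of the miRNA.
    """
    rng = config.rng()
    n_ages = len(config.ages)
    sample_ids = [
        f"age{age:g}w_rep{rep + 1}"
        for age in config.ages
        for rep in range(config.n_per_age)
    ]
    samples = pd.DataFrame(
        {
            "age_weeks": np.repeat(np.asarray(config.ages, dtype=float), config.n_per_age),
            "replicate": np.tile(np.arange(1, config.n_per_age + 1), n_ages),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    n_samples = len(sample_ids)

    # geometric trajectory of the miRNA mean across age groups
    young_mean = 50.0
    ratios = config.mirna_fold_change ** (np.arange(n_ages) / (n_ages - 1))
    mirna_means = young_mean * ratios
    mirna = np.repeat(mirna_means, config.n_per_age) * np.exp(
        config.noise_sigma * rng.standard_normal(n_samples)
    )
    mirna = pd.Series(mirna, index=samples.index, name="mirna")

    log2_mirna = np.log2(mirna.to_numpy())
    sd = log2_mirna.std()
    z = (log2_mirna - log2_mirna.mean()) / sd if sd > 0 else np.zeros(n_samples)

    gene_ids = [f"gene{i + 1:05d}" for i in range(config.n_genes)]
    baselines = np.exp(rng.normal(np.log(20.0), 1.0, size=config.n_genes))
    target_idx = rng.choice(config.n_genes, size=config.n_targets, replace=False)
    is_target = np.zeros(config.n_genes, dtype=bool)
    is_target[target_idx] = True

    log2_expr = np.log2(baselines)[:, None] + np.zeros((config.n_genes, n_samples))
    log2_expr[is_target] -= config.coupling * z[None, :]
    noise = config.noise_sigma * rng.standard_normal((config.n_genes, n_samples))
    values = np.exp2(log2_expr) * np.exp(noise)

    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                            columns=samples.index),
        samples=samples,
    )
    truth = GroundTruth(
        target_gene_ids=frozenset(gene_ids[i] for i in target_idx)
    )
    return expr, mirna, truth


#: sign of log2FC per type, as (aging, sponge); types partition the
#: intersection of the two DEG lists by direction of regulation.
TYPE_SIGNS = {1: (1, 1), 2: (1, -1), 3: (-1, -1), 4: (-1, 1)}


def simulate_deg_tables(
    type_counts: Sequence[int],
    extra_nonoverlap: Sequence[int] = (0, 0),
    config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Two DEG tables (aging and sponge contrasts) with a planted typing.

    Exactly ``type_counts[t-1]`` genes of type ``t`` appear in both tables
    with the type's sign pattern; ``extra_nonoverlap`` adds genes present
    in only the aging or only the sponge table. |log2FC| is drawn as
    ``max(0.1, |N(1, 0.25)|)`` so signs are never ambiguous; p-values and
    FDR are drawn uniformly below 0.05 (the tables model already-filtered
    DEG lists).
    """
    if len(type_counts) != 4 or any(c < 0 for c in type_counts):
        raise ConfigError("type_counts must be four nonnegative integers")
    if len(extra_nonoverlap) != 2 or any(c < 0 for c in extra_nonoverlap):
        raise ConfigError("extra_nonoverlap must be two nonnegative integers")
    rng = (config or SimulationConfig()).rng()

    def magnitudes(n: int) -> np.ndarray:
        return np.maximum(0.1, np.abs(rng.normal(1.0, 0.25, size=n)))

    rows_aging, rows_sponge, gene_types = [], [], {}
    counter = 0

    def new_gene() -> str:
        nonlocal counter
        counter += 1
        return f"deg{counter:05d}"

    for gene_type, count in zip((1, 2, 3, 4), type_counts):
        sign_aging, sign_sponge = TYPE_SIGNS[gene_type]
        for _ in range(count):
            gene = new_gene()
            gene_types[gene] = gene_type
            rows_aging.append((gene, sign_aging * magnitudes(1)[0]))
            rows_sponge.append((gene, sign_sponge * magnitudes(1)[0]))
    for table_rows, count in zip((rows_aging, rows_sponge), extra_nonoverlap):
        for _ in range(count):
            gene = new_gene()
            sign = rng.choice([-1, 1])
            table_rows.append((gene, sign * magnitudes(1)[0]))

    def to_table(rows: list[tuple[str, float]]) -> pd.DataFrame:
        n = len(rows)
        return pd.DataFrame(
            {
                "gene_id": [g for g, _ in rows],
                "log2FC": [fc for _, fc in rows],
                "PValue": rng.uniform(0, 0.01, size=n),
                "FDR": rng.uniform(0, 0.05, size=n),
            }
        )

    truth = GroundTruth(gene_types=gene_types)
    return to_table(rows_aging), to_table(rows_sponge), truth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def simulate_smallrna_reads(
    ref: MatureReference,
    config: SimulationConfig,
) -> tuple[list[Read], GroundTruth]:
    """Small-RNA reads: (mature +/- 3' shift) + adapter, with errors and Ns.

    Each read's source miRNA is drawn uniformly from the reference; its 3'
    end is shifted by an offset drawn from ``isomir_len_shift`` (negative:
    truncation; positive: non-templated extension with random bases, the
    isomiR case that makes a read longer than its mature reference), the
    full adapter is appended, and per-base substitution errors / N calls
    are applied at the configured rates. Qualities are constant Phred 40.
    """
    if len(ref) == 0:
        raise InputError("empty mature reference")
    rng = config.rng()
    ids = list(ref.entries)
    shifts = np.array(list(config.isomir_len_shift.keys()))
    probs = np.array(list(config.isomir_len_shift.values()), dtype=float)

    reads: list[Read] = []
    truth = GroundTruth()
    for i in range(config.read_count):
        mirna_id = ids[rng.integers(len(ids))]
        mature = ref[mirna_id]
        shift = int(shifts[rng.choice(len(shifts), p=probs)])
        if shift >= 0:
            insert = mature + _random_seq(rng, shift)
        else:
            if len(mature) + shift < 1:
                raise ConfigError("isomiR truncation longer than the mature sequence")
            insert = mature[: len(mature) + shift]
        seq = np.array(list(insert + config.adapter))
        errors = rng.random(len(seq)) < config.error_rate
        if errors.any():
            # substitute with a uniformly chosen *different* base
            for pos in np.flatnonzero(errors):
                choices = [b for b in "ACGT" if b != seq[pos]]
                seq[pos] = choices[rng.integers(3)]
        ns = rng.random(len(seq)) < config.n_rate
        seq[ns] = "N"
        read_id = f"read{i + 1:06d}"
        reads.append(Read(read_id, "".join(seq), "I" * len(seq)))
        truth.read_sources[read_id] = mirna_id
    return reads, truth


def simulate_utrs(
    n: int,
    planted_sites: Mapping[int, Sequence[tuple[int, str]]],
    seed: SeedDefinition,
    config: SimulationConfig | None = None,
    utr_length: int = 200,
) -> tuple[dict[str, str], GroundTruth]:
    """Random-background UTRs with seed sites planted at known coordinates.

    ``planted_sites`` maps a UTR index (0-based) to ``(position, class)``
    pairs, class in {"8mer", "7mer-m8", "7mer-A1"}. Backgrounds are
    rejection-sampled until they contain no accidental seed site, so the
    scanner's output equals the planted truth exactly.
    """
    rng = (config or SimulationConfig()).rng()
    patterns = {
        "8mer": seed.site_8mer,
        "7mer-m8": seed.site_7mer_m8,
        "7mer-A1": seed.site_7mer_a1,
    }
    utrs: dict[str, str] = {}
    truth = GroundTruth()
    for i in range(n):
        utr_id = f"utr{i + 1:04d}"
        wanted = list(planted_sites.get(i, ()))
        for pos, site_class in wanted:
            if site_class not in patterns:
                raise InputError(f"unknown site class {site_class!r}")
            if pos < 0 or pos + len(patterns[site_class]) > utr_length:
                raise InputError(
                    f"site at {pos} does not fit in a {utr_length} nt UTR"
                )
        for _attempt in range(1000):
            bases = list(_random_seq(rng, utr_length))
            for pos, site_class in wanted:
                pattern = patterns[site_class]
                bases[pos : pos + len(pattern)] = pattern
            candidate = "".join(bases)
            found = {(s.start, s.site_class) for s in scan_utr(candidate, seed, utr_id)}
            if found == {(pos, cls) for pos, cls in wanted}:
                break
        else:
            raise InputError(f"could not build UTR {utr_id} without spurious sites")
        utrs[utr_id] = candidate
        truth.planted_sites[utr_id] = wanted
    return utrs, truth
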