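"""Seed-match scanning of 3'-UTRs, binding-site mutagenesis and sponge design.

A canonical miRNA target site is the Watson-Crick reverse complement of the
miRNA *seed* (nucleotides 2-8 from the miRNA 5' end) found on the sense
strand of a 3'-UTR. Three site classes are recognised, in decreasing
strength:

* ``8mer``     -- perfect match to positions 2-8 plus an ``A`` opposite
  miRNA position 1;
* ``7mer-m8``  -- perfect match to positions 2-8;
* ``7mer-A1``  -- perfect match to positions 2-7 plus the position-1 ``A``.

No G:U wobble pairing is allowed anywhere. Coordinates are 0-based
half-open on the given sequence's sense strand throughout.

The sponge designer builds a decoy transcript: tandem repeats of the full
reverse complement of the mature miRNA in which the four bases pairing
miRNA positions 9-12 are substituted to non-complementary bases. The
resulting central bulge prevents Ago2-mediated slicing of the sponge while
retaining perfect seed pairing, so the construct sequesters the miRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import InputError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
#: Transversion of the complementary base (A<->C, G<->T): deterministic,
#: always breaks Watson-Crick pairing with the original partner.
_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize(seq: str, what: str) -> str:
    seq = seq.upper().replace("U", "T")
    if not set(seq) <= set("ACGTN"):
        raise InputError(f"{what}: non-nucleotide characters in {seq!r}")
    return seq


@dataclass(frozen=True)
class SeedDefinition:
    """A mature miRNA and its seed region (1-based inclusive, default 2-8)."""

    mature: str
    seed_start: int = 2
    seed_end: int = 8

    def __post_init__(self) -> None:
        object.__setattr__(self, "mature", _normalize(self.mature, "mature miRNA"))
        if "N" in self.mature:
            raise InputError("mature miRNA sequence may not contain N")
        if len(self.mature) < 8:
            raise InputError("mature miRNA must be at least 8 nt")
        if (self.seed_start, self.seed_end) != (2, 8):
            raise InputError("only the canonical 2-8 seed is supported")

    @property
    def seed(self) -> str:
        """Seed sequence, miRNA positions 2-8 (5'->3')."""
        return self.mature[1:8]

    # Site patterns as they appear 5'->3' on the target strand. The miRNA
    # pairs antiparallel, so position 1 faces the 3' end of the site.
    @property
    def site_7mer_m8(self) -> str:
        return revcomp(self.mature[1:8])

    @property
    def site_8mer(self) -> str:
        return self.site_7mer_m8 + "A"

    @property
    def site_7mer_a1(self) -> str:
        return revcomp(self.mature[1:7]) + "A"


@dataclass(frozen=True)
class SeedSite:
    utr_id: str
    start: int
    end: int
    site_class: str  # {"8mer", "7mer-m8", "7mer-A1"}


def scan_utr(utr: str, seed: SeedDefinition, utr_id: str = "utr") -> list[SeedSite]:
    """Report every canonical seed site in a UTR, sorted by start.

    Each start position is assigned its strongest class; a ``7mer-A1``
    wholly contained in an already-reported ``8mer`` is suppressed so a
    single biological site is never reported twice. ``N`` never matches.
    Overlapping distinct sites are all reported.
    """
    utr = _normalize(utr, f"UTR {utr_id!r}")
    sites: list[SeedSite] = []
    p8, p7m8, p7a1 = seed.site_8mer, seed.site_7mer_m8, seed.site_7mer_a1
    m8_base = p7m8[0]  # base pairing miRNA position 8
    for start in range(len(utr) - 6):
        if utr[start : start + 8] == p8:
            sites.append(SeedSite(utr_id, start, start + 8, "8mer"))
        elif utr[start : start + 7] == p7m8:
            sites.append(SeedSite(utr_id, start, start + 7, "7mer-m8"))
        elif utr[start : start + 7] == p7a1:
            if start > 0 and utr[start - 1] == m8_base:
                continue  # tail of an 8mer reported at start-1
            sites.append(SeedSite(utr_id, start, start + 7, "7mer-A1"))
    return sites


def mutate_site(
    utr: str,
    site: SeedSite,
    n_mut: int = 3,
    rng_seed: int = 0,
    seed: SeedDefinition | None = None,
) -> str:
    """Substitute ``n_mut`` bases inside a seed site to abolish it.

    Positions within the site window are chosen with a seeded RNG and each
    base is replaced by the transversion of itself (A<->C, G<->T), which
    breaks its Watson-Crick pairing with the miRNA. The mutated sequence is
    rescanned when a :class:`SeedDefinition` is supplied and the position
    subset is advanced deterministically until no site overlaps the window,
    so the knockout is guaranteed, not probabilistic. Output length always
    equals input length and differs from the input at exactly ``n_mut``
    positions.
    """
    utr = _normalize(utr, f"UTR {site.utr_id!r}")
    if not (0 <= site.start < site.end <= len(utr)):
        raise InputError("site does not lie within the UTR")
    if n_mut == 0:
        return utr
    window = list(range(site.start, site.end))
    if n_mut > len(window):
        raise InputError("n_mut exceeds the site width")
    rng = np.random.default_rng(rng_seed)
    combos = list(combinations(window, n_mut))
    rng.shuffle(combos)
    for positions in combos:
        bases = list(utr)
        for pos in positions:
            bases[pos] = _TRANSVERSION[bases[pos]]
        mutated = "".join(bases)
        if seed is None:
            return mutated
        hits = scan_utr(mutated, seed, site.utr_id)
        if not any(h.start < site.end and h.end > site.start for h in hits):
            return mutated
    raise InputError("could not abolish the site with the requested n_mut")


@dataclass(frozen=True)
class SpongeParams:
    """Sponge architecture: tandem bulged binding sites.

    ``bulge_start``/``bulge_end`` are 1-based inclusive miRNA positions
    whose pairing is broken (default 9-12, immediately 3' of the seed).
    """

    repeats: int = 7
    bulge_start: int = 9
    bulge_end: int = 12
    spacer: str = "CATT"

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise InputError("repeats must be >= 1")
        if self.bulge_end - self.bulge_start + 1 != 4:
            raise InputError("bulge must span exactly 4 miRNA positions")
        object.__setattr__(self, "spacer", _normalize(self.spacer, "spacer"))


@dataclass
class SpongeConstruct:
    sequence: str
    site_coords: list[tuple[int, int]]
    #: per site: miRNA position (1-based) -> construct index of the paired base
    pairing_maps: list[dict[int, int]] = field(default_factory=list)


# Fallback spacers tried in order if one creates a spurious seed site at a
# site/spacer junction; all are deterministic so constructs are reproducible.
_SPACER_CANDIDATES = ("CATT", "CTTA", "ACCA", "TCAC", "GATC")


def design_sponge(seed: SeedDefinition, params: SpongeParams | None = None) -> SpongeConstruct:
    """Build a miRNA sponge: ``repeats`` bulged antisense sites joined by spacers.

    Each site is the reverse complement of the full mature sequence with
    the four bases pairing miRNA positions ``bulge_start``-``bulge_end``
    transverted to non-complementary bases; seed pairing (positions 1-8)
    is left perfect so a seed scan of the construct recovers every site.
    """
    params = params or SpongeParams()
    mature = seed.mature
    if len(mature) < 12:
        raise InputError("mature miRNA must be >= 12 nt for a bulged sponge")

    length = len(mature)
    site = list(revcomp(mature))
    for mirna_pos in range(params.bulge_start, params.bulge_end + 1):
        idx = length - mirna_pos  # antiparallel pairing: pos 1 <-> site 3' end
        site[idx] = _TRANSVERSION[site[idx]]
    site_seq = "".join(site)

    spacers = [params.spacer] + [s for s in _SPACER_CANDIDATES if s != params.spacer]
    for spacer in spacers:
        construct = spacer.join([site_seq] * params.repeats)
        coords, maps = [], []
        step = length + len(spacer)
        for i in range(params.repeats):
            start = i * step
            coords.append((start, start + length))
            maps.append({pos: start + length - pos for pos in range(1, length + 1)})
        # the scan must recover exactly one seed site per repeat, inside it
        hits = scan_utr(construct, seed, "sponge")
        ok = len(hits) == params.repeats and all(
            any(s <= h.start and h.end <= e for (s, e) in coords) for h in hits
        )
        if ok:
            return SpongeConstruct(construct, coords, maps)
    raise InputError("no spacer candidate yields a clean sponge construct")
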