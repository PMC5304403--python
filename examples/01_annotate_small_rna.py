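"""Preprocess and annotate simulated small-RNA reads.

Generates 500 reads from five mature miRNAs (each read is its mature
sequence plus the 3' sequencing adapter, with isomiR length variation),
cleans them (N filter, adapter trim, 18-33 nt size filter) and quantifies
them with the two-phase annotator. Phase 1 places whole reads inside a
mature sequence; phase 2 rescues 3'-extended isomiRs that are longer than
their reference.
"""

from mirage import MatureReference, SimulationConfig, annotate, preprocess
from mirage.pipeline import EXAMPLE_MATURE_MIRNAS
from mirage.simulate import simulate_smallrna_reads

ref = MatureReference(EXAMPLE_MATURE_MIRNAS.items())
cfg = SimulationConfig(read_count=500, error_rate=0.002, n_rate=0.002, rng_seed=42)
reads, truth = simulate_smallrna_reads(ref, cfg)

clean, stats = preprocess(reads)
print(f"preprocessing: {stats}")

assignments, table = annotate(clean, ref)
phase2 = sum(a.phase == 2 for a in assignments)
print(f"per-miRNA counts: {table.counts}  unassigned: {table.unassigned}")
print(f"{phase2} reads annotated in phase 2 (3'-extended isomiRs)")

correct = sum(truth.read_sources[a.read_id] == a.mirna_id for a in assignments)
print(f"{correct}/{len(assignments)} assignments match the generator's truth")
# Counts plus unassigned always equal the preprocessed read number; on
# low-error reads essentially every read returns to its source miRNA.
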