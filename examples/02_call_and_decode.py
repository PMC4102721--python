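"""Call pool signals by thresholds and decode them into clone coordinates.

A pool is evaluated only when its normalised intensity R is at least 0.2;
Theta <= 0.05 calls assay nucleotide 1, Theta >= 0.95 nucleotide 2, and
anything between means the pool holds clones of both nucleotides.  A
coordinate is reported for a nucleotide when all seven of its pools are
positive for it.
"""

from homoeopool import (Simulation, SimulationConfig, call_table,
                        plate_summary, screen_all, summarize_screen)

sim = Simulation.generate(SimulationConfig(
    region_length_bp=100_000, n_plates=12, rows_per_plate=8,
    cols_per_plate=12, insert_size_mean_bp=25_000, insert_size_sd_bp=2_500,
    insert_size_min_bp=5_000, coverage_target=8.0, n_assays=20,
    diagonal_modulus=7, seed=42))

calls = call_table(sim.signals)
print(plate_summary(calls).head(5).to_string(index=False))

score_table, per_assay = screen_all(calls, sim.design)
print("\nper-assay putative clone counts (first five assays):")
print(per_assay.head(5).to_string(index=False))

summary = summarize_screen(score_table)
print(f"\ntotal scores: {summary.n_scores}, "
      f"distinct putative clones: {summary.n_clones}")
print("multiplicity histogram (clones identified by exactly k assays):")
print(summary.histogram_all.to_dict())

# Most putative coordinates are 'shadows' whose seven pools happen to be
# covered by the union of true positives — the reason downstream
# selection and amplicon validation exist.
truth = sim.truth_scores()
print(f"\ntrue detectable scores: {len(truth)} "
      f"(decoded table contains {len(score_table)})")
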