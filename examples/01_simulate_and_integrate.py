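"""Simulate a noisy DAD injection and recover the peak areas.

Builds a three-analyte chromatogram (triene, diene, monoene anacardic
acids) with detector noise and baseline drift, runs the full peak pipeline
(baseline -> detect -> integrate -> match -> purity), and compares the
integrated areas with the simulator's ground truth.
"""

from anacquant import SimulationRecipe, default_catalog, simulate_chromatogram
from anacquant.peaks import process_chromatogram

recipe = SimulationRecipe(concentrations=(20.0, 15.0, 60.0),
                          noise_sd=0.05, baseline_offset=2.0,
                          baseline_drift=0.3, seed=42)
chrom, truths = simulate_chromatogram(recipe)
peaks = process_chromatogram(chrom, default_catalog())

truth_by_name = {t.analyte.name: t for t in truths}
print(f"{'analyte':<10} {'RT/min':>7} {'area':>12} {'truth':>12} "
      f"{'err%':>7} {'purity':>7}")
for p in peaks:
    if p.assigned_analyte is None:
        continue
    t = truth_by_name[p.assigned_analyte.name]
    err = 100 * (p.area - t.true_area) / t.true_area
    print(f"{p.assigned_analyte.name:<10} {p.apex_time:>7.2f} {p.area:>12.1f} "
          f"{t.true_area:>12.1f} {err:>7.2f} {p.purity:>7.4f}")

# Areas land within ~1% of the simulated truth despite noise and drift, and
# purity stays near 1 because each peak contains a single compound.
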