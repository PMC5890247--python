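"""Full five-stage occlusion-reperfusion protocol analysis of a synthetic
cohort.

Simulates eight eyes through BASELINE -> ECAO -> Reperfuse1 -> ICAO ->
Reperfuse2 with the calibrated stage effects (a strong external carotid
effect, a negligible internal carotid effect), runs the whole pipeline,
and prints the vessel-ROI stage summary with paired-test markers plus the
reperfusion-gate outcomes.
"""
from lsfg import (AnalysisConfig, PhantomConfig, StageEffects,
                  generate_protocol_cohort, run_full_analysis)

config = PhantomConfig(height=36, width=75, duration_s=0.4,
                       pulse_rate_hz=2.5)
sessions = generate_protocol_cohort(n_eyes=8, n_vessels_per_eye=3,
                                    effects=StageEffects(), config=config,
                                    seed=11, n_recordings=3)
report = run_full_analysis(sessions, AnalysisConfig())

vessel = report.stage_summaries.query("roi_label == 'VESSEL'")
tests = report.paired_tests.query("roi_label == 'VESSEL'")
print("stage        mean MBR    sd     sem    n   vs baseline")
for _, row in vessel.iterrows():
    t = tests[tests.stage == row["stage"]]
    marker = t.iloc[0]["marker"] if len(t) else ""
    print(f"{row['stage']:11s} {row['mean']:8.2f} {row['sd']:6.2f} "
          f"{row['sem']:6.2f} {row['n']:4d}   {marker}")
print()
print(report.gates[["animal_id", "eye", "relative_deviation",
                    "reperfusion_ok"]].to_string(index=False))
# '**' marks p < 0.001 against baseline.  ECAO collapses flow to ~27
# percent of baseline; the later stages recover to within a few percent,
# yet vessel-level pairing is sensitive enough to flag even those small
# residual deficits.  The gate column verifies that flow returned to
# within +/-20 percent of baseline before the second occlusion was
# analysed.
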