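"""Run the full synthetic validation experiment end to end.

Simulates the default cohort (10 specimens, true BV/TV evenly spread over
10-45%), calibrates the MR cortical threshold on a pure-cortical block,
measures every specimen on both modalities, and computes the agreement
statistics — the same loop the cadaveric study performs on real knees.
"""

from trabmorph.pipeline import run_synthetic_experiment

res = run_synthetic_experiment(seed=1)

table = res.truth.merge(res.measurements, on=["id", "side"])
print(table.round(2).to_string(index=False))
print()
print(f"calibrated cortical threshold: {res.calibration.threshold:.2f}")
rep = res.agreement
print(f"Spearman rho (MR vs microCT) = {rep.spearman_rho:.3f} "
      f"(95% CI {rep.ci_low:.2f} to {rep.ci_high:.2f})")
print(f"Bland-Altman bias (MR - microCT) = {rep.bland_altman.bias:.2f} pp")

# Expected behaviour: microCT tracks the generated truth to within ~0.1 pp,
# MR preserves the ranking (rho ~ 1) but underestimates every specimen, so
# the bias is strongly negative — the synthetic cohort reproduces the
# qualitative signature of the cadaveric validation.
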