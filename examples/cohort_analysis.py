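"""Full cohort analysis on a synthetic study.

Simulates the default cohort (30 PD tappers of whom 20 complete follow-up,
19 controls, 8 songs split 4 high- / 4 low-groove: 552 trials), then runs
the complete analysis: per-trial entropy, random-intercept mixed models
compared by likelihood-ratio tests, UPDRS change z-scores correlated with
baseline entropy, and BAT d' group comparison.
"""

import groovetap as gt
from groovetap.pipeline import analyze_cohort, effect_directions

bundle = gt.simulate_cohort(seed=42)
results = analyze_cohort(bundle.tap_trials, bundle.updrs, bundle.bat,
                         bundle.participants, bundle.reference_periods)

print(f"trials analysed: {results['exclusions']['n_trials']}, of which "
      f"{results['exclusions']['n_trials_with_long_ioi']} had a gap > 3 s")
print()
print("mean trial entropy (H, log10 units):")
for key, s in sorted(results["entropy_summary"].items()):
    print(f"  {key:<12} {s['mean_H']:.3f} +- {s['sd_H']:.3f}  (n={s['n_trials']})")

print()
print("likelihood-ratio tests on log(Entropy), random intercept per participant:")
for term, res in results["entropy_lme"].items():
    print(f"  {term:<11} chi2({res['df']}) = {res['chi_sq']:6.2f}, "
          f"p = {res['p']:.2e}, coef = {res['coef']:+.3f}")

print()
corr = results["updrs"]["baseline_entropy_vs_change_z"]
for groove, c in corr.items():
    print(f"baseline entropy vs UPDRS change z ({groove}-groove): "
          f"r = {c['r']:+.3f}, p = {c['p']:.3g}")
print(f"mean UPDRS change (post - pre): "
      f"{results['updrs']['mean_delta']:+.1f} points")

print()
bat = results["bat"]["group_means"]
wt = results["bat"]["welch_t_pd_vs_control"]
print(f"BAT d': PD {bat['pd']['d_prime']:.2f} vs control "
      f"{bat['control']['d_prime']:.2f} "
      f"(Welch t({wt['df']:.1f}) = {wt['t']:.2f}, p = {wt['p']:.3f})")

print()
print("encoded effect directions recovered:", effect_directions(results))
print()
print("A positive groove/time_point coefficient means the alphabetically "
      "later level (low groove, pre) has higher entropy; negative 'de' "
      "means dance experience lowers entropy; positive r means tighter "
      "baseline coupling predicts larger UPDRS improvement.")
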