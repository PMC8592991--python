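"""Detect daily torpor from body-temperature and VO2 recordings.

Generates a three-day trace (6-min grid) for one animal with a torpor bout
on day 2 in which VO2 drops to 30% of baseline and T_B relaxes toward
ambient. Day 1 defines the animal's own circadian baseline (two-harmonic
Bayesian regression); a time point is torpid when every recorded signal
falls below the lower bound of the 99.9% posterior-predictive interval and
lies in the second half of the day (ZT 12-24).
"""

from fitcage import physio as ph
from fitcage import synthdata as sd

trace, truth = sd.gen_physio(animal_id="m1", seed=3,
                             bouts=[(24 + 14.0, 24 + 18.0, 0.3)])
posteriors = {sig: ph.fit_baseline(trace, sig, draws=2000, seed=3)
              for sig in ("tb", "vo2")}
for sig, post in posteriors.items():
    print(f"{sig}: posterior median mesor = {post.mesor.mean():.2f}, "
          f"residual sd = {post.sigma.mean():.3f}, R-hat = {post.rhat:.3f}")

calls = ph.detect_torpor(trace, posteriors, ci=0.999)
n_torpid = int(calls["torpor"].sum())
print(f"{n_torpid} of {len(calls)} time points labeled torpid "
      f"({n_torpid / 10:.1f} h; true bout was 4 h starting ZT-14 on day 2)")

min_tb, min_vo2 = ph.min_phenotype(trace, calls)
print(f"minimal phenotype during torpor: T_B = {min_tb:.1f} degC, "
      f"VO2 = {min_vo2:.2f} mL/min")
print("(these minima are the per-animal inputs to the KO phenotype model)")
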