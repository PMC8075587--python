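"""Dynamic beat under viscous drag: the spinning-lasso torsion signature.

Integrates the beat equations for a traveling-wave dynein actuation, once
with the paraflagellar rod attached (nu = 3) and once without (the
Chlamydomonas-like control).  The rod-bearing beat carries torsional peaks
of alternating sign traveling from base to tip; the rod-free beat is planar.
"""

import numpy as np

from lassobeat import RunConfig
from lassobeat.pipelines import run_beat

cfg = RunConfig()
for pfr_free, label in [(False, "with rod"), (True, "rod-free")]:
    res = run_beat(cfg, pfr_free=pfr_free)
    s = res["summary"]
    tau_lo, tau_hi = s["tau_extremes"]
    print(f"{label:9s} converged={s['converged_periodic']} "
          f"(mismatch {s['period_mismatch']:.1e})  "
          f"tau*L range [{tau_lo:+.1f}, {tau_hi:+.1f}]  "
          f"peak tracks: {s['n_tracks']}  "
          f"speeds {['%+.1f' % v for v in s['track_speeds']]}")

print()
print("tau*L is the nondimensional centerline torsion over the beat.  With")
print("the rod, both positive and negative torsion peaks coexist and travel")
print("at positive speed (base to tip) - the geometric signature of the")
print("euglenid 'spinning lasso'.  Without the rod the beat is planar and")
print("torsion-free, like a Chlamydomonas flagellum.")
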