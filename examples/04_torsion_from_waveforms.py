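"""Curvature/torsion analysis of 3D waveforms (the measured-beat pipeline).

Generates a synthetic helix waveform with known curvature and torsion,
writes it in the standard waveform CSV schema, and runs the same discrete
Frenet analysis that would be applied to reconstructed flagellar shapes.
"""

import tempfile
from pathlib import Path

import numpy as np

from lassobeat.fixtures import generate_fixture
from lassobeat.pipelines import torsion_analysis

with tempfile.TemporaryDirectory() as tmp:
    prefix = Path(tmp) / "helix"
    payload = generate_fixture("helix", prefix, n_points=200,
                               params={"a": 1.0, "b": 0.3})
    truth = payload["truth"]
    [ct] = torsion_analysis(prefix.with_suffix(".csv"))
    m = ct.valid_mask
    print(f"ground truth:  kappa = {truth['kappa']:.4f}  tau = {truth['tau']:.4f}")
    print(f"recovered:     kappa = {ct.kappa[m].mean():.4f}  "
          f"tau = {ct.tau[m].mean():.4f}")
    print(f"max rel errors: kappa {np.abs(ct.kappa[m]-truth['kappa']).max()/truth['kappa']:.2%}, "
          f"tau {np.abs(ct.tau[m]-truth['tau']).max()/truth['kappa']:.2%}")

print()
print("A right-handed helix of radius a and pitch 2 pi b has constant")
print("kappa = a/(a^2+b^2) and tau = b/(a^2+b^2) > 0; the discrete estimator")
print("recovers both within a percent at 200 sample points, validating the")
print("torsion sign convention and accuracy of the waveform pipeline.")
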