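"""Walk one trial through the signal pipeline: filter, angle, segment, features.

Prints the detected stretch-reflex onset against the planted truth and the
first analysis window's 20-dimensional feature vector.
"""

import numpy as np

from spastiq.kinematics import correct_drift, integrate_gyro
from spastiq.pipeline import process_trial
from spastiq.features import FEATURE_NAMES
from spastiq.synth import CohortSpec, make_profiles, make_trial

spec = CohortSpec(master_seed=42)
profile = [p for p in make_profiles(spec) if p.mas_numeric == 1.5][0]
rec, truth = make_trial(profile, "fast", trial_index=12, spec=spec, subject_index=7)

windows, trial_row = process_trial(rec)

traj = correct_drift(integrate_gyro(rec.filtered().gyro, rec.fs))
print(f"trial {rec.trial_id} (MAS {rec.mas_label}, {rec.velocity_class} stretch)")
print(f"  max elbow angle      : {traj.theta.max():6.1f} deg")
print(f"  peak angular velocity: {trial_row['peak_velocity']:6.1f} deg/s")
print(f"  planted burst onset  : {truth['true_onset_angle']:6.1f} deg")
print(f"  detected onset       : {trial_row['onset_angle']:6.1f} deg "
      f"({trial_row['onset_source']})")
print(f"  analysis windows     : {trial_row['n_windows']} x 128 ms (64 ms step)\n")

first = windows[0]
print("first window features (RMS in uV, MPF in Hz):")
for name in ("rms_bb", "rms_tb", "wl_bb", "ar4_bb", "mpf_bb", "mpf_tb"):
    print(f"  {name:8s} = {first[name]:9.3f}")
print("\nThe flexor channels (bb/br/ba) carry the reflex burst, so their RMS and")
print("waveform length dwarf the quiet extensor (tb); MPF reflects the burst's")
print("severity-shifted frequency band.")
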