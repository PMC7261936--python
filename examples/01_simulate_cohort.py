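"""Generate a small synthetic stretch-trial cohort and inspect its ground truth.

Each subject gets passive elbow-stretch trials at three velocities; patient
trials carry a stretch-reflex sEMG burst whose onset angle, amplitude and
spectral band encode the simulated MAS grade.
"""

from spastiq.synth import CohortSpec, make_cohort

spec = CohortSpec(
    n_per_level={0.0: 1, 1.0: 1, 1.5: 1, 2.0: 1},
    trials_per_class={"slow": 1, "normal": 1, "fast": 2},
    master_seed=42,
)
trials, truth = make_cohort(spec)

print(f"{len(trials)} trials from {truth.subject_id.nunique()} subjects\n")
print(truth[["trial_id", "velocity_class", "mas_numeric",
             "true_onset_angle", "true_peak_velocity"]].round(1).to_string(index=False))
print("\ntrue_onset_angle is the elbow angle (deg) at which the reflex burst was")
print("planted (NaN for the healthy subject, who has no burst); true_peak_velocity")
print("is the peak extension speed in deg/s — faster stretches trigger the burst")
print("at smaller angles, the velocity dependence that defines spasticity.")
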