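"""Simulate one subject and extract the preregistered ERP measures.

Injects known component amplitudes (the study's group means), adds AR(1)
noise and artifact epochs, runs baseline correction, rereferencing,
range-based artifact rejection and measure extraction, and compares the
recovered measures with the injected truth.
"""

from mmnload import compose_session, preprocess_and_measure, simulate_subject
from mmnload.synthetic_eeg import NoiseSpec, SubjectGroundTruth

truth = SubjectGroundTruth("S01", {
    ("n1", "low"): -0.49, ("n1", "high"): -0.15,
    ("oddball_mmn", "low"): -2.13, ("oddball_mmn", "high"): -2.26,
    ("corrected_mmn", "low"): -1.38, ("corrected_mmn", "high"): -1.26,
    ("p3a", "low"): 0.41, ("p3a", "high"): -0.18,
    ("visual_p3", "low"): 9.29, ("visual_p3", "high"): 2.73,
}, wmc_pcu=0.72)

session = compose_session(seed=7)
epochs = simulate_subject(session, truth, NoiseSpec(sd=3.0), fs=256.0, seed=7)
print(f"simulated {epochs.n_epochs} epochs, "
      f"{len(epochs.channels)} channels, nose reference")

measures = preprocess_and_measure(epochs, "S01")
print(f"artifact cutoff: {measures.retention.cutoff_uv:.1f} uV; "
      f"minimum cell retention: {measures.retention.min_primary_retention:.1%} "
      f"(excluded below 70%)\n")
print("measure          load   recovered   injected")
for (name, load), value in sorted(measures.measures.items()):
    injected = truth.amplitude(name if name != "p3a_exploratory" else "p3a", load)
    print(f"{name:<16s} {load:<5s} {value:9.2f}  {injected:9.2f}")
print("\nrecovered values deviate from the injected truth only by the "
      "epoch-noise standard error (microvolts).")
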