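"""Simulate a synthetic balance-test cohort and write it to disk.

Generates 28 healthy and 32 parkinsonian subjects (60 s of two-channel COP
displacement each, 100 Hz) from regime-switching generators with known
parameters, then writes one CSV per subject plus a manifest.
"""

from pathlib import Path

from swayhmm import CohortSimConfig, simulate_cohort, write_cop_file, write_manifest

out = Path("scratch/example_cohort")
config = CohortSimConfig(seed=1)  # 28 + 32 subjects, 60 s at 100 Hz, separation 1.0
cohort = simulate_cohort(config)

out.mkdir(parents=True, exist_ok=True)
for seq in cohort.sequences:
    write_cop_file(seq, out / f"{seq.subject_id}.csv")
manifest_path = write_manifest(cohort.manifest, out / "manifest.csv")

first = cohort.sequences[0]
print(f"cohort: {len(cohort.healthy)} healthy + {len(cohort.pd)} PD subjects")
print(f"each recording: {first.n} samples = {first.duration_s:.0f} s "
      f"at {first.sampling_rate_hz:.0f} Hz, channels {first.channels}")
print(f"manifest: {manifest_path}")
# The per-subject CSVs hold time + ML/AP displacement in mm; the hidden
# regime paths and the true generator parameters stay available on the
# returned cohort object for ground-truth experiments.
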