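"""Simulate the study cohort and archive it as EDF + ground truth.

Generates four groups (healthy controls, Parkinson's without FOG, with mild
and with severe FOG; 3 subjects x 15 cued ankle-dorsiflexion trials each)
with the default group profiles: controls carry the strongest early MRCP
slope (NS1) and beta-band desynchronization, severe freezers a near-flat NS1,
suppressed low-beta ERD, pre-movement theta ERS and the weakest TA burst.

Writes EDF sessions to scratch/cohort/ (consumed by the later scripts) and
the injected per-trial ground truth to results/cohort_ground_truth.tsv.
"""

from pathlib import Path

from mrcplab.edf import write_session
from mrcplab.synth import default_profiles, generate_cohort

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
SEED = 20240101


def main() -> None:
    COHORT_DIR.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    sessions, truth = generate_cohort(default_profiles(), 3, n_trials=15,
                                      seed=SEED)
    for sess in sessions:
        write_session(sess, COHORT_DIR / f"{sess.subject_id}.edf")
    truth.trials.to_csv(RESULTS / "cohort_ground_truth.tsv", sep="\t",
                        index=False)
    per_group = truth.trials.groupby("group").agg(
        subjects=("subject_id", "nunique"), trials=("trial", "size"),
        mean_ns1=("ns1_uv_per_s", "mean"), mean_peak=("peak_uv", "mean"))
    print(f"wrote {len(sessions)} sessions ({len(truth.trials)} trials) "
          f"to {COHORT_DIR}")
    print(per_group.round(2).to_string())


if __name__ == "__main__":
    main()
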