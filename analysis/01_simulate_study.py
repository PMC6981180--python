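"""Simulate the synthetic comparative study.

Three rat-like animals (lymph node + spleen) and two human-like subjects,
8,000 reads per compartment from 6,000 clones each, written as AIRR TSVs
under results/study/ for the downstream analysis scripts.
"""

from study_common import STUDY_DIR, simulate_study, pooled


def main() -> None:
    study = simulate_study(force=True)
    print(f"wrote study to {STUDY_DIR}")
    for sid, rep in pooled(study).items():
        prod = rep.productive()
        print(f"  {sid} ({study[sid]['preset']}): {len(rep)} reads, "
              f"{len(prod)} productive ({len(prod) / len(rep):.1%})")


if __name__ == "__main__":
    main()
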