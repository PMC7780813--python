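"""Generate the synthetic study materials: canonical fixture traces with
ground-truth manifests and a rendered dual-channel demo movie.

Everything is regenerable from the seed, so the bulky artifacts (traces,
the TIFF movie, tidy screen tables) live under scratch/ where the later
steps read them; a small ground-truth summary goes to results/.
"""

from pathlib import Path

import pandas as pd

from cardiomap.pipeline import make_fixtures

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "scratch" / "fixtures"
    paths = make_fixtures(seed=1, out_dir=out)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    summaries = []
    for label in ("atrial", "ventricular"):
        for kind in ("ap", "cat"):
            man = pd.read_csv(out / f"{label}_{kind}_manifest.csv")
            row = man.iloc[0].to_dict()
            row.update({"subtype": label, "channel": kind})
            summaries.append(row)
    pd.DataFrame(summaries).to_csv(results / "ground_truth_summary.csv", index=False)

    print("synthetic study materials:")
    for name, path in sorted(paths.items()):
        print(f"  {name:<28} {path.relative_to(ROOT)}")
    man = pd.read_csv(out / "atrial_ap_manifest.csv")
    print(
        f"\natrial ground truth (beat 0): APD20/50/80 = "
        f"{man.apd20[0]:.1f}/{man.apd50[0]:.1f}/{man.apd80[0]:.1f} ms"
    )
    man = pd.read_csv(out / "ventricular_ap_manifest.csv")
    print(
        f"ventricular ground truth (beat 0): APD20/50/80 = "
        f"{man.apd20[0]:.1f}/{man.apd50[0]:.1f}/{man.apd80[0]:.1f} ms"
    )


if __name__ == "__main__":
    main()
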