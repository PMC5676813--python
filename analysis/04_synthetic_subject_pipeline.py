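"""End-to-end geometry check on synthetic subjects.

Builds mirrored gyrified-sphere hemispheres with a parallel white/pial
pair (known thickness) and six sector regions, runs the full metrics
extraction (IC skew, CT, LGI, SA per region and hemisphere), and prints
the recovered values against the construction's ground truth.  Writes
results/synthetic_subject_metrics.tsv.
"""

import argparse
from pathlib import Path

from cortmorph.regions import subject_metrics
from cortmorph.synthetic import make_synthetic_subject


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--level", type=int, default=4, help="mesh refinement level")
    ap.add_argument("--thickness", type=float, default=2.5)
    ap.add_argument("--amplitude", type=float, default=3.0)
    args = ap.parse_args()

    subj = make_synthetic_subject(level=args.level, thickness=args.thickness,
                                  amplitude=args.amplitude)
    pairs = {h: p for h, (p, _) in subj.items()}
    labelings = {h: lab for h, (_, lab) in subj.items()}
    table = subject_metrics("synthetic01", pairs, labelings)

    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "synthetic_subject_metrics.tsv", sep="\t", index=False,
                 float_format="%.10g")

    mean_rows = table[table.hemisphere == "mean"]
    print(mean_rows[["region", "ic_skew", "ct_mean", "lgi_mean", "sa"]]
          .to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print(f"\nconstruction thickness {args.thickness} mm; recovered CT "
          f"{mean_rows.ct_mean.min():.3f}-{mean_rows.ct_mean.max():.3f} mm "
          f"(finite facets bias the closest-distance estimate low at coarse levels)")


if __name__ == "__main__":
    main()
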