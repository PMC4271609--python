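#!/usr/bin/env python
"""Six pairwise cross-modal comparisons on one phantom session.

Aligns the four per-contact value sets over the common recording-contact
targets (stim pair and anything within 10 mm of the seed excluded), computes
the Pearson r^2 and p for every modality pair, and writes the comparison
matrix plus a 2x3 scatter panel.
"""

import argparse
from pathlib import Path

from quadconn import crossmodal
from quadconn.phantom import PhantomConfig, build_phantom
from quadconn.workflow import MeasureParams, contact_targets, measure_all

AXIS_UNITS = {
    "ccep": "CCEP (uV)",
    "rsfmri": "rsfMRI (r)",
    "desfmri": "DES-fMRI (|t|)",
    "dmri": "dMRI (0-10)",
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--no-plot", action="store_true")
    args = ap.parse_args()

    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    ph = build_phantom(PhantomConfig(rng_seed=args.seed))
    params = MeasureParams()
    values = measure_all(ph, params)
    targets = contact_targets(ph, params)
    matrix = crossmodal.comparison_matrix(values, targets)
    matrix.to_csv(out / "comparison_matrix.tsv", sep="\t", index=False,
                  float_format="%.10g")
    print(f"comparison matrix ({len(targets.identifiers)} targets) -> "
          f"{out / 'comparison_matrix.tsv'}")
    print(matrix.to_string(index=False))

    if not args.no_plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 3, figsize=(12, 7))
        for ax, row in zip(axes.ravel(), matrix.itertuples()):
            pc = crossmodal.compare(values[row.modality_a], values[row.modality_b],
                                    targets, row.modality_a, row.modality_b)
            ax.scatter(pc.values_a, pc.values_b, s=12, alpha=0.7)
            ax.set_xlabel(AXIS_UNITS[row.modality_a])
            ax.set_ylabel(AXIS_UNITS[row.modality_b])
            ax.set_title(f"$r^2$={row.r2:.3f}  p={row.p:.2g}", fontsize=10)
        fig.tight_layout()
        fig_path = out / "figures" / "pairwise_scatter.png"
        fig_path.parent.mkdir(exist_ok=True)
        fig.savefig(fig_path, dpi=120)
        print(f"scatter panel -> {fig_path}")


if __name__ == "__main__":
    main()
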