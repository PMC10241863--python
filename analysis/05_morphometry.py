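#!/usr/bin/env python
"""Embryo morphometrics: axis speeds and fibre density on synthetic data.

Reads results/synthetic/landmarks/ and results/synthetic/fibre_images/;
writes results/morphometry.csv and results/fibre_density.csv; prints
recovery against generator truth and the coverage-ordering check.
"""

from pathlib import Path

import pandas as pd
from scipy.stats import spearmanr

from vitellometrics import (
    convergence_speed,
    elongation_speed,
    fibre_density,
    segmentation_speed,
)
from vitellometrics.io import read_fibre_image, read_landmark_series

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    truth = pd.read_csv(RESULTS / "synthetic" / "landmark_truth.csv").set_index(
        "sample_id"
    )
    rows = []
    for path in sorted((RESULTS / "synthetic" / "landmarks").glob("*.csv")):
        series = read_landmark_series(path)
        rows.append(
            {
                "sample_id": path.stem,
                "day": truth.loc[path.stem, "day"],
                "elongation_um_h": elongation_speed(series),
                "convergence_um_h": convergence_speed(series),
                "segmentation_per_h": segmentation_speed(series),
            }
        )
    morpho = pd.DataFrame(rows)
    morpho.to_csv(RESULTS / "morphometry.csv", index=False)
    print("speed recovery by group (mean vs truth):")
    for day, grp in morpho.groupby("day"):
        t = truth[truth.day == day].iloc[0]
        print(
            f"  {day}: elong {grp.elongation_um_h.mean():.1f} "
            f"(truth {t.elongation_um_h:.0f}), conv {grp.convergence_um_h.mean():.1f} "
            f"(truth {t.convergence_um_h:.0f}), seg {grp.segmentation_per_h.mean():.3f} "
            f"(truth {t.seg_rate_per_h:.3f}) um/h, pairs/h; n={len(grp)}"
        )

    fibre_truth = pd.read_csv(RESULTS / "synthetic" / "fibre_truth.csv")
    frows = []
    for rec in fibre_truth.itertuples():
        image = read_fibre_image(RESULTS / "synthetic" / "fibre_images" / rec.image)
        res = fibre_density(image, n_rois=16, roi_size=192, seed=1)
        frows.append(
            {
                "image": rec.image,
                "day": rec.image.split(".")[0],
                "coverage_true": rec.coverage_true,
                "density": res.density,
            }
        )
    fibres = pd.DataFrame(frows)
    fibres.to_csv(RESULTS / "fibre_density.csv", index=False)
    rho, _ = spearmanr(fibres.coverage_true, fibres.density)
    print(f"fibre density vs generated coverage: Spearman rho = {rho:.3f}")


if __name__ == "__main__":
    main()
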