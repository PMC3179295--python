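#!/usr/bin/env python
"""Align the cohort outlines and fit the point-distribution model.

Reads the landmark file written by 01_simulate_cohort.py, applies the
acceptability filter, runs generalized Procrustes alignment (tangent
projection on), fits the 10-mode PCA shape model and scores every subject
in SD units.  Writes the aligned cohort, model, scores and a +/-2 SD mode
gallery under results/shape/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from hipshape.io import filter_acceptable, read_landmarks
from hipshape.model import fit_shape_model, mode_gallery, score_subjects
from hipshape.procrustes import generalized_procrustes

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "shape"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    landmarks = read_landmarks(ROOT / "cohort" / "landmarks.csv")
    kept, report = filter_acceptable(landmarks)
    print(f"acceptability filter: kept {report.n_kept}/{report.n_total} "
          f"({report.percent_excluded}% excluded)")

    aligned = generalized_procrustes(kept)
    print(f"GPA converged in {aligned.iterations_run} iterations")
    aligned.to_json(OUT / "aligned.json")

    model = fit_shape_model(aligned, m=10)
    model.to_json(OUT / "shape_model.json")
    pct = 100.0 * model.variance_fractions.sum()
    print(f"10 modes capture {pct:.1f}% of total shape variance")
    print("per-mode variance fractions:",
          np.round(model.variance_fractions, 3).tolist())

    scores = score_subjects(model, aligned)
    scores.frame().to_csv(OUT / "mode_scores.csv", index=False)
    s = scores.sd_units
    print(f"score standardization: max |mean| = {np.abs(s.mean(0)).max():.2e}, "
          f"max |SD-1| = {np.abs(s.std(0, ddof=1) - 1).max():.2e}")

    for j in (1, 4):
        fig, ax = plt.subplots(figsize=(4, 4))
        for sd, style in zip((-2.0, 0.0, 2.0), ("C0--", "k-", "C3:")):
            pts = mode_gallery(model, j, (sd,))[0].reshape(-1, 2)
            closed = np.vstack([pts, pts[:1]])
            ax.plot(closed[:, 0], closed[:, 1], style,
                    label="mean" if sd == 0 else f"{sd:+.0f} SD")
        ax.set_aspect("equal")
        ax.legend(fontsize=8)
        ax.set_title(f"Mode {j} at +/-2 SD")
        fig.savefig(OUT / f"gallery_mode{j}.svg")
        plt.close(fig)
    print(f"mode galleries written to {OUT}")


if __name__ == "__main__":
    main()
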