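"""The cells-versus-depth subsampling trade-off experiment.

For the deep regime, subsamples cells (fixed original order) at 1/4, 1/2,
3/4 and all of the 66 cells; for the shallow regime, thins each cell's
counts to X% of its original total (X = 10, 25, 50, 75, 100) with the
original order fixed. Each scenario runs 25 replicates; the error is the
published MSE over 500 randomly sampled genes between the scaled 9-zone
profiles of the perturbed and full data. A line plot goes to scratch/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from zonerecon import qc_io
from zonerecon.containers import CellOrder
from zonerecon.tradeoff import SubsamplingScenario, run_tradeoff_grid, summarize_tradeoff

BASE = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
SEED = 1


def load_order(matrix, name):
    tab = pd.read_csv(BASE / f"order_{name}.tsv", sep="\t").set_index("cell_id")
    pos = tab.loc[list(matrix.cell_ids), "position"].to_numpy(int)
    return CellOrder(np.argsort(pos), oriented=True)


def main() -> None:
    all_results = []
    deep = qc_io.read_expression(BASE / "data" / "deep.csv")
    order_d = load_order(deep, "deep")
    n = deep.n_cells
    scns = [SubsamplingScenario(mode="cells", level=lev, replicates=25,
                                n_mse_genes=500, seed=SEED) for lev in (n // 4, n // 2, 3 * n // 4, n)]
    res = run_tradeoff_grid(deep, scns, order=order_d).assign(regime="deep")
    all_results.append(res)

    shallow = qc_io.read_expression(BASE / "data" / "shallow.csv")
    order_s = load_order(shallow, "shallow")
    scns = [SubsamplingScenario(mode="depth", level=x, replicates=25,
                                n_mse_genes=500, seed=SEED) for x in (0.10, 0.25, 0.50, 0.75, 1.00)]
    res = run_tradeoff_grid(shallow, scns, order=order_s).assign(regime="shallow")
    all_results.append(res)

    tidy = pd.concat(all_results, ignore_index=True)
    tidy.to_csv(BASE / "tradeoff_replicates.tsv", sep="\t", index=False)
    summary = (
        tidy.groupby(["regime", "mode", "level"])["mse"].agg(["mean", "std"]).reset_index()
    )
    summary.to_csv(BASE / "tradeoff_summary.tsv", sep="\t", index=False)
    for _, row in summary.iterrows():
        print(f"{row['regime']:8s} {row['mode']:5s} level {row['level']:>6}: "
              f"mean MSE {row['mean']:.3f} (sd {row['std']:.3f})")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        SCRATCH.mkdir(exist_ok=True)
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        for ax, (regime, mode) in zip(axes, (("deep", "cells"), ("shallow", "depth"))):
            sub = summary[(summary["regime"] == regime) & (summary["mode"] == mode)]
            ax.errorbar(sub["level"], sub["mean"], yerr=sub["std"], marker="o")
            ax.set_xlabel("cells retained" if mode == "cells" else "depth fraction")
            ax.set_ylabel("profile MSE")
            ax.set_title(f"{regime} regime, {mode} subsampling")
        fig.tight_layout()
        fig.savefig(SCRATCH / "tradeoff_curves.png", dpi=120)
        print(f"plot written to {SCRATCH / 'tradeoff_curves.png'}")
    except Exception as exc:  # plotting is best-effort
        print(f"plot skipped: {exc}")


if __name__ == "__main__":
    main()
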