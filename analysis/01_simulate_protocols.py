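"""Simulate the study's protocol regimes from one zonated ground truth.

Generates a 1000-gene truth with latent pericentral->periportal cell
positions and a 15-gene marker panel, then simulates a deep full-length-style
protocol (66 cells, mean depth 1e5) and a shallow droplet-style protocol
(606 cells, mean depth 5e3). Writes the matrices, marker table and truth
tables under results/data/ for the downstream steps.
"""

from pathlib import Path

import zonerecon as zr
from zonerecon import qc_io, simulate

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = zr.generate_truth(n_genes=1000, n_cells=66, seed=SEED)
    deep, shallow = zr.simulate_protocol_set(
        truth, [zr.DEFAULT_REGIMES["deep"], zr.DEFAULT_REGIMES["shallow"]]
    )
    qc_io.write_expression(deep, OUT / "deep.csv")
    qc_io.write_expression(shallow, OUT / "shallow.csv")
    qc_io.write_markers(truth.markers(), OUT / "markers.tsv")
    simulate.write_truth(truth, OUT / "truth_cells.tsv", OUT / "truth_genes.tsv")

    for name, m in (("deep", deep), ("shallow", shallow)):
        depth = m.values.sum(axis=0)
        print(
            f"{name}: {m.n_cells} cells, median depth {int(depth.mean())}, "
            f"{(m.values > 0).sum(axis=0).mean():.0f} genes detected per cell on average"
        )


if __name__ == "__main__":
    main()
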