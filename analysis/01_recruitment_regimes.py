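"""Regulated recruitment away from equilibrium: affinity-tunable duality.

Sweeps the 4-state TF/Pol recruitment model with the printed incoherent
parameter set (TF enhances Pol recruitment, reduces its activity) over a
grid of TF unbinding rates bT (inverse affinity) and concentrations x.
Finding: the response over a fixed concentration window is increasing at
weak binding, nonmonotonic in between, and decreasing at tight binding,
with the nonmonotonic peak moving to higher concentration as affinity
drops.  Writes the class-per-row table and the fold-change grid to
results/.
"""

import pathlib

import numpy as np

from txduality.recruitment import incoherent_reference_params, recruitment_rate_sweep
from txduality.response import log_grid, regime_map

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    bT_grid = log_grid(1e-3, 1e2, 25)
    x_grid = log_grid(1e-1, 1e3, 25)

    def row(bT: float, xs: np.ndarray) -> np.ndarray:
        rates = recruitment_rate_sweep(
            incoherent_reference_params(bT=bT), np.concatenate(([0.0], xs))
        )
        return rates[1:] / rates[0]

    m = regime_map(row, "bT", bT_grid, "x", x_grid)

    OUT.mkdir(exist_ok=True)
    m.to_frame().to_csv(OUT / "recruitment_regime_classes.csv", index=False)
    m.fold_change_frame().to_csv(OUT / "recruitment_fold_change_grid.csv")

    counts = {c: m.classes.count(c) for c in sorted(set(m.classes))}
    print("recruitment model, incoherent reference parameters")
    print(f"  response classes across bT rows: {counts}")
    peaks = [p for c, p in zip(m.classes, m.peak_inputs) if c == "nonmonotonic"]
    print(f"  nonmonotonic band: {len(peaks)} rows, peak x from "
          f"{peaks[0]:.3g} to {peaks[-1]:.3g} nM (nondecreasing: "
          f"{bool(np.all(np.diff(peaks) >= 0))})")
    print(f"  wrote {OUT / 'recruitment_regime_classes.csv'}")


if __name__ == "__main__":
    main()
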