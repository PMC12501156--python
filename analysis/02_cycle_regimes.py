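"""Transcription-cycle model: nonmonotonicity without nonequilibrium binding.

Sweeps the 6-state cycle model (printed incoherent set: TF accelerates
activation 15-fold, slows completion 100-fold) over unbinding rate and
concentration.  The TF does not touch the recruitment step (e1 = e1r = 1),
so TF/Pol binding satisfies detailed balance; the dissipation of the
transcription cycle alone supports all three response classes.
"""

import pathlib

import numpy as np

from txduality.cycle import cycle_rate_sweep, reference_incoherent_cycle_params
from txduality.response import log_grid, regime_map

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    def row(bT: float, xs: np.ndarray) -> np.ndarray:
        rates = cycle_rate_sweep(
            reference_incoherent_cycle_params(bT=bT), np.concatenate(([0.0], xs))
        )
        return rates[1:] / rates[0]

    m = regime_map(row, "bT", log_grid(1e-3, 1e2, 25), "x", log_grid(1e-1, 1e3, 25))

    OUT.mkdir(exist_ok=True)
    m.to_frame().to_csv(OUT / "cycle_regime_classes.csv", index=False)
    m.fold_change_frame().to_csv(OUT / "cycle_fold_change_grid.csv")

    counts = {c: m.classes.count(c) for c in sorted(set(m.classes))}
    p = reference_incoherent_cycle_params()
    print("transcription-cycle model, incoherent reference parameters "
          f"(e2={p.e2}, e3={p.e3}, binding at detailed balance)")
    print(f"  response classes across bT rows: {counts}")
    print(f"  wrote {OUT / 'cycle_regime_classes.csv'}")


if __name__ == "__main__":
    main()
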