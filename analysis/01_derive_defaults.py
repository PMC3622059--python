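#!/usr/bin/env python
"""Re-derive every frozen model constant and check it against the package.

The sensor's dark-pool parameters, the in-cell apparent EC50/ratio anchor,
and all tuned transport strengths are solved numerically from the published
observations (two inhibition points per wavelength, the calibration dynamic
range, the printed half-times and assay amplitudes).  This script re-runs
those solves from scratch and writes the comparison with the constants
frozen in clsense.configs.

Runtime: ~1 min (the transport solves root-find full simulations).
"""

from pathlib import Path

import pandas as pd

from clsense import calibrate, configs

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    solved = calibrate.derive_all(verbose=True)
    solved["FUROSEMIDE_BLOCK"] = solved.get(
        "FUROSEMIDE_BLOCK", calibrate.solve_furosemide_block()
    )
    rows = []
    for name, value in solved.items():
        frozen = getattr(configs, name)
        rel = abs(value - frozen) / max(abs(frozen), 1e-12)
        rows.append(dict(constant=name, solved=value, frozen=frozen,
                         rel_difference=rel))
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "derived_constants.csv", index=False)
    print(df.to_string(index=False))
    worst = df.rel_difference.max()
    print(f"\nlargest relative difference vs frozen constants: {worst:.2e}")
    assert worst < 5e-3, "frozen constants drifted from their derivation"


if __name__ == "__main__":
    main()
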