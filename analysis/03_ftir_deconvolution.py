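"""Amide-I secondary-structure recovery on synthetic silk-like spectra.

Generates 20 seeded spectra of the default six-band mixture (56% total
β-sheet) at SNR 50, deconvolves each, and tabulates the recovered class
fractions against the generator truth, plus the spectral correlation
coefficient of representative β-sheet-rich vs random-coil-rich spectra.
Output: results/ftir_recovery.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from silkscale import ftir
from silkscale.synthetic import (FTIRBand, FTIRSpectrumConfig,
                                 gen_ftir_spectrum)

OUT = Path(__file__).resolve().parent.parent / "results"


def main(n_rep: int = 20) -> None:
    recovered: dict[str, list[float]] = {}
    truth = None
    for seed in range(n_rep):
        s, t = gen_ftir_spectrum(FTIRSpectrumConfig(seed=seed))
        truth = t
        res = ftir.deconvolve(s, seed=seed)
        for label in t["fractions"]:
            recovered.setdefault(label, []).append(res.fractions.get(label, 0.0))
        recovered.setdefault("total β-sheet", []).append(res.total_beta)

    rows = []
    for label, frac in {**truth["fractions"],
                        "total β-sheet": truth["total_beta"]}.items():
        est = np.array(recovered[label])
        rows.append({
            "class": label,
            "true_percent": frac,
            "mean_recovered": est.mean(),
            "sd_recovered": est.std(ddof=1),
            "worst_abs_error": np.abs(est - frac).max(),
        })
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "ftir_recovery.csv", index=False)
    print(df.to_string(index=False))

    beta, _ = gen_ftir_spectrum(
        FTIRSpectrumConfig(bands=(FTIRBand(1624.0, 100.0),), snr=None))
    coil, _ = gen_ftir_spectrum(
        FTIRSpectrumConfig(bands=(FTIRBand(1648.0, 100.0),), snr=None))
    print(f"\nR(spectrum, itself)          = "
          f"{ftir.correlation_coefficient(beta, beta):.6f}")
    print(f"R(β-sheet-rich, coil-rich)   = "
          f"{ftir.correlation_coefficient(beta, coil):.3f}")


if __name__ == "__main__":
    main()
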