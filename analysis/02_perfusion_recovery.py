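"""Characterize oSVD deconvolution accuracy over planted (CBF, MTT) grids.

Sweeps mean transit time at three noise levels (noiseless, SNR 100, SNR 50)
and reports bias and RMSE of the recovered CBF, the standard validation
figure for DSC deconvolution.  Writes results/perfusion_recovery.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from strokefate.validation import recover_cbf, simulate_recovery_voxels

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    rows = []
    for snr in (None, 100.0, 50.0):
        for mtt in (2.0, 4.0, 6.0, 8.0, 10.0):
            exp = simulate_recovery_voxels(
                400, seed=seed + int(mtt * 10) + int(snr or 0),
                mtt_range=(mtt, mtt), snr=snr,
            )
            err = recover_cbf(exp)
            rows.append({
                "snr": "inf" if snr is None else int(snr),
                "mtt_s": mtt,
                "bias_pct": float(np.mean(err)),
                "rmse_pct": float(np.sqrt(np.mean(err**2))),
                "n_voxels": len(err),
            })
    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "perfusion_recovery.csv", index=False)
    print(df.round(2).to_string(index=False))
    noiseless = df[df.snr == "inf"]
    print(f"\nnoiseless |bias| stays below "
          f"{noiseless.bias_pct.abs().max():.1f}% across MTT 2-10 s")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
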