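#!/usr/bin/env python
"""Screen yield-sensitive derivative bands and wavelet cells, per growth stage.

On the training trial: correlates every FD band and every (scale, band)
wavelet cell with plot yield, writes the full correlation maps and the
greedily selected predictors, and prints the strongest cell per stage.
"""

from pathlib import Path

import pandas as pd

from paddywave.features import StageTransforms
from paddywave.screening import band_yield_correlation, critical_r, select_sensitive, wavelet_yield_correlation
from paddywave.spectra_io import STAGES, read_spectra, read_yields
from paddywave.synthetic_data import SynthConfig, simulate_trial

TRIALS = Path(__file__).resolve().parent.parent / "results" / "trials"
OUT = Path(__file__).resolve().parent.parent / "results" / "screening"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    if (TRIALS / "yields_train.csv").exists():
        sets = {st: read_spectra(TRIALS / f"spectra_train_{st}.csv", "wide", stage=st) for st in STAGES}
        yields = read_yields(TRIALS / "yields_train.csv")
    else:
        sets, yields, _ = simulate_trial(SynthConfig(), SEED)

    selected_rows = []
    for stage in STAGES:
        t = StageTransforms.from_spectraset(sets[stage], with_cwt=True)
        fd_map = band_yield_correlation((t.plot_ids, t.wavelengths, t.fd), yields)
        r_min = critical_r(fd_map.n, 0.05)
        fd_sel = select_sensitive(fd_map, r_min, top_k=5)
        fd_map.table.to_csv(OUT / f"corr_fd_{stage}.csv", index=False, float_format="%.5g")

        w_map = wavelet_yield_correlation(t.plot_ids, t.scales, t.wavelengths, t.cwt, yields)
        w_sel = select_sensitive(w_map, r_min, top_k=5)
        w_map.table.to_csv(OUT / f"corr_cwt_{stage}.csv", index=False, float_format="%.5g")

        for nm in fd_sel:
            selected_rows.append({"stage": stage, "kind": "FD", "scale": "", "wavelength_nm": nm})
        for sc, nm in w_sel:
            selected_rows.append({"stage": stage, "kind": "CWT", "scale": int(sc), "wavelength_nm": nm})

        fd_best, w_best = fd_map.best(), w_map.best()
        print(
            f"{stage:>10}: FD best r={fd_best['r']:+.2f} at {int(fd_best['wavelength_nm'])} nm | "
            f"CWT best r={w_best['r']:+.2f} at scale {int(w_best['scale'])}, "
            f"{int(w_best['wavelength_nm'])} nm | critical |r|={r_min:.3f}"
        )
    pd.DataFrame(selected_rows).to_csv(OUT / "selected_predictors.csv", index=False)
    print(f"wrote correlation maps and selections to {OUT}")


if __name__ == "__main__":
    main()
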