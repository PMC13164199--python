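#!/usr/bin/env python
"""Generate the synthetic study data: the GC-IMS volatile census and the NIR
acquisitions on both instrument grids.

Emulates the storage experiment: 7 coix-seed samples (raw S + processed
stored 2..56 months), 50 diffuse-reflectance spectra per sample on each of
the 900-1700 nm (228-point) and 1300-2500 nm (257-point) grids, and
74 volatile compounds (+ 2-octanol-D internal standard) x 3 GC-IMS
replicates per sample.

Large data tables go to scratch/run-data/ (regenerable from the seed); a
small design summary is printed and written under results/.
"""

from pathlib import Path

import pandas as pd

from chemocal import RunConfig
from chemocal.synthetic import generate_peak_table, generate_spectra

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "run-data"
RESULTS = ROOT / "results"


def main() -> None:
    config = RunConfig(seed=1)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    table = generate_peak_table(config.design, config.volatile, seed=config.seed)
    table.to_csv(SCRATCH / "peak_table.csv")
    analytes = table.analytes.data
    print(f"GC-IMS table: {analytes['cas'].nunique()} compounds "
          f"({analytes['compound'].nunique()} M/D signals), "
          f"{analytes['sample'].nunique()} samples x 3 replicates")

    rows = []
    for rng_name in config.range_names:
        spectra = generate_spectra(
            config.design, config.spectral_config_for_range(rng_name), seed=config.seed
        )
        spectra.to_csv(SCRATCH / f"spectra_{rng_name}.csv")
        print(f"NIR {rng_name} nm: {spectra.n_spectra} spectra x "
              f"{spectra.n_wavelengths} wavelengths")
        rows.append({
            "range": rng_name,
            "n_spectra": spectra.n_spectra,
            "n_wavelengths": spectra.n_wavelengths,
            "samples": spectra.meta["sample"].nunique(),
        })
    pd.DataFrame(rows).to_csv(RESULTS / "design_summary.csv", index=False)
    print(f"data -> {SCRATCH}, summary -> {RESULTS / 'design_summary.csv'}")


if __name__ == "__main__":
    main()
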