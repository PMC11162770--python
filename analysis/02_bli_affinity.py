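#!/usr/bin/env python
"""ssDNA-binding affinity from BLI sensorgrams.

Simulates the published experimental design - a 4-concentration analyte
panel (0.625, 1.5, 2.5, 5 nM), 300 s association / 600 s dissociation -
around the measured 60-mer affinity (K_d = 1.17 nM), and fits all phases
globally with the 1:1 Langmuir model. With 1% noise the global fit returns
K_d within a few percent, showing the panel identifies the rate constants.

Writes results/02_bli_affinity.json.
"""

import json
from pathlib import Path

from ssbdyn import bulk, simulate

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 200


def main():
    true = bulk.BindingFit1to1(k_on_per_M_s=1e6, k_off_per_s=1.17e-3, R_max_nm=1.0)
    out = {"generating": true.to_dict()}
    for label, noise in [("noiseless", 0.0), ("1pct_noise", 0.01)]:
        traces, _ = simulate.gen_bli_traces(true, noise_sd_nm=noise, seed=SEED)
        fit = bulk.fit_bli_global(traces)
        out[label] = fit.to_dict()
        print(f"{label}: k_on={fit.k_on_per_M_s:.3g} /M/s  "
              f"k_off={fit.k_off_per_s:.3g} /s  K_d={fit.K_d_nM:.3f} nM")
    print(f"generating K_d = {true.K_d_nM:.2f} nM "
          "(60-mer poly-dT operating point)")
    OUT.mkdir(exist_ok=True)
    (OUT / "02_bli_affinity.json").write_text(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
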