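#!/usr/bin/env python
"""Calibrate the folding + repression model from the scored phenotypes.

Anchors the model's experiment-specific constants to the dataset's own
measurements: the unrepressed ceiling GFP_max from the nonsense variants,
the auto-fluorescence floor GFP_auto from the requirement that the inferred
wild-type total-repressor ratio between the two expression conditions
equals the measured 15:1 ratio, and the expressed concentrations CI_E from
the wild-type phenotype and the wild-type folded fraction (K_fold = 114).

Reads results/phenotypes.tsv, writes results/params_calibrated.yaml.
"""

import argparse
from pathlib import Path

import pandas as pd

from cidms import thermo, workflow
from cidms.thermo import ThermoParams

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()
    path = RESULTS / "phenotypes.tsv"
    if not path.exists():
        raise SystemExit("run 02_score_phenotypes.py first")
    phen = pd.read_csv(path, sep="\t", keep_default_na=False)
    params = workflow.calibrate_params_from_phenotypes(phen, ThermoParams.default())
    params.to_yaml(RESULTS / "params_calibrated.yaml")

    f_n_wt = float(thermo.fraction_folded(params.dgf_wt, params))
    print(f"wild-type folding: dG_F = {params.dgf_wt:.3f} kcal/mol, "
          f"f_N = {f_n_wt:.4f} (K_fold = {params.k_fold_wt:.0f})")
    print(f"GFP ceiling (nonsense weighted mean): "
          f"{params.log2_gfp_max:.2f} log2 AU")
    print(f"auto-fluorescence floor from the 15:1 expression ratio: "
          f"{params.log2_gfp_auto:.2f} log2 AU "
          f"({2 ** params.log2_gfp_auto:.1f} AU)")
    print(f"expressed repressor: CI_E_low = {params.ci_e_low:.3e} M, "
          f"CI_E_high = {params.ci_e_high:.3e} M")
    print(f"wrote {RESULTS / 'params_calibrated.yaml'}")


if __name__ == "__main__":
    main()
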