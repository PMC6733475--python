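"""Effect of interaction range: entropy of seeded range-restricted fits as the
allowed coupling range W grows, on (i) the synthetic family, (ii) the
independent-sites control, and (iii) the non-interacting-repeats control.
The controls verify the estimation procedure: an independent-sites dataset
shows no entropy decrease with W, and a dataset without inter-repeat
couplings shows no drop at the repeat length W = L.

Writes results/range_sweep/{family,independent_control,noninteracting_control}.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import repeatscape as rs

RESULTS = Path(__file__).resolve().parent.parent / "results" / "range_sweep"
FAMILY = Path(__file__).resolve().parent.parent / "results" / "family"
SEED = 2026
WS = [0, 1, 2, 3, 4, 5, 6, 8, 11]


def sweep(obs, label, seed):
    cfg = rs.FitConfig(n_samples=20000, thinning=120, max_iters=300,
                       eps_id=1.0, seed=seed)
    models, reports = rs.fit_range_sweep(obs, cfg, WS, fit_lambda=True)
    rows = []
    for W, m, rep in zip(WS, models, reports):
        res = rs.entropy_thermodynamic(m, n=20000, alpha_grid=np.linspace(0, 1, 21),
                                       thinning=120, seed=seed + 100 + W)
        rows.append({"W": W, "S_bits": res.S_bits, "mc_error_bits": res.mc_error_bits,
                     "converged": rep.converged, "iterations": rep.iterations})
        print(f"  {label} W={W:2d}: S = {res.S_bits:.3f} +- {res.mc_error_bits:.3f}")
    return pd.DataFrame(rows)


def main():
    RESULTS.mkdir(parents=True, exist_ok=True)

    print("synthetic family:")
    aln = rs.read_alignment(FAMILY / "alignment.fa", L=6, alphabet="ABC-")
    obs = rs.compute_observables(aln)
    sweep(obs, "family", SEED + 11).to_csv(RESULTS / "family.tsv", sep="\t", index=False)

    print("independent-sites control:")
    ind = rs.make_planted_model(rs.PlantedSpec(L=6, q=4, coupling_density=0.0,
                                               seed=SEED + 20))
    obs_i = rs.compute_observables(rs.make_planted_alignment(ind, 20000, seed=SEED + 21))
    df = sweep(obs_i, "indep", SEED + 22)
    df.to_csv(RESULTS / "independent_control.tsv", sep="\t", index=False)
    print(f"  flatness: max decrease {df.S_bits.iloc[0] - df.S_bits.min():.3f} bits")

    print("non-interacting-repeats control:")
    nir = rs.make_planted_model(rs.PlantedSpec(L=6, q=4, n_couplings=10,
                                               intra_frac=1.0, seed=SEED + 30))
    obs_n = rs.compute_observables(rs.make_planted_alignment(nir, 20000, seed=SEED + 31))
    df = sweep(obs_n, "nir", SEED + 32)
    df.to_csv(RESULTS / "noninteracting_control.tsv", sep="\t", index=False)
    at = df.set_index("W").S_bits
    print(f"  drop at W=L: {at[5] - at[6]:.3f} bits (expect ~0)")


if __name__ == "__main__":
    main()
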