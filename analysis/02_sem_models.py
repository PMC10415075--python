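"""Fit the theory SEM and its two competitors to the healthy cohort.

Reports the global chi-square, fit indices, the standardized structural
solution, the model comparison, and the four product-of-paths indirect
effects (delta-method p values).  Writes results/sem_fits.json and
results/sem_comparison.csv.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from reguframe.cohort import read_cohort  # noqa: E402
from reguframe.sem import (  # noqa: E402
    build_alternative_models,
    build_theory_model,
    compare_models,
    fit_sem,
    indirect_effect,
)

RESULTS = ROOT / "results"

CHAINS = {
    "prevention->calm->involvement": ["prevention", "calm", "involvement"],
    "promotion->calm->involvement": ["promotion", "calm", "involvement"],
    "prevention->hope->involvement": ["prevention", "hope", "involvement"],
    "promotion->hope->involvement": ["promotion", "hope", "involvement"],
}


def main() -> None:
    table = read_cohort(RESULTS / "cohort_healthy.csv")
    theory = build_theory_model()
    alt1, alt2 = build_alternative_models()
    fits = [fit_sem(s, table) for s in (theory, alt1, alt2)]

    for fit in fits:
        idx = fit.indices
        print(f"{fit.spec.name}: chi2({fit.df}) = {fit.chi_square:.2f}, "
              f"RMSEA {idx['rmsea']:.3f}, CFI {idx['cfi']:.3f}, "
              f"TLI {idx['tli']:.3f}, SRMR {idx['srmr']:.3f}, "
              f"converged={fit.converged}")
    comparison = compare_models(fits)
    print("\nmodel comparison (ranked):")
    print(comparison.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    comparison.to_csv(RESULTS / "sem_comparison.csv", index=False)

    fit = fits[0]
    print("\nstandardized structural solution (theory model):")
    for a, b in theory.structural:
        key = f"{a}->{b}"
        se = fit.se.get(key, float("nan"))
        print(f"  {key}: {fit.estimates[key]:+.3f} (se {se:.3f})")

    indirect = {}
    print("\nindirect effects (product of paths):")
    for name, chain in CHAINS.items():
        res = indirect_effect(fit, chain)
        indirect[name] = res
        print(f"  {name}: {res['estimate']:+.3f} (se {res['se']:.3f}, p {res['p']:.4f})")

    (RESULTS / "sem_fits.json").write_text(json.dumps({
        "fits": [
            {"model": f.spec.name, "n": f.n, "chi_square": f.chi_square,
             "df": f.df, "indices": f.indices, "converged": f.converged,
             "estimates": f.estimates, "se": f.se}
            for f in fits
        ],
        "indirect_effects": indirect,
        "comparison": comparison.to_dict(orient="records"),
    }, indent=2))
    print(f"\nwrote {RESULTS / 'sem_fits.json'}")


if __name__ == "__main__":
    main()
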