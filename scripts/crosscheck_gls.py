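#!/usr/bin/env python
"""Compare the varIdent GLS engine against R's nlme::gls on a shared fixture.

Not a runtime dependency of the package: this is the documented cross-check
that the profiled ML/REML likelihood, coefficients, residual sd and variance
ratios agree with the reference implementation (requires Rscript with the
nlme and jsonlite packages on PATH).

Usage: python scripts/crosscheck_gls.py [--seed 42] [--n-per-group 10]
"""

from __future__ import annotations

import argparse
import json
import subprocess
import sys
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from bioturbaton.gls import ModelSpec, fit  # noqa: E402

R_CODE = """
suppressMessages(library(nlme))
d <- read.csv("{csv}")
d$grp <- factor(d$grp)
out <- list()
for (m in c("ML", "REML")) {{
  f <- gls(response ~ grp, data = d, weights = varIdent(form = ~1 | grp), method = m)
  out[[m]] <- list(logLik = as.numeric(logLik(f)), AIC = AIC(f),
                   beta = as.numeric(coef(f)), sigma = f$sigma,
                   ratios = as.numeric(coef(f$modelStruct$varStruct,
                                            uncons = FALSE, allCoef = TRUE)),
                   se = as.numeric(sqrt(diag(vcov(f)))))
}}
cat(jsonlite::toJSON(out, digits = 12, auto_unbox = TRUE))
"""


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--n-per-group", type=int, default=10)
    args = ap.parse_args()

    rng = np.random.default_rng(args.seed)
    groups = ["a", "b", "c", "d"]
    sds = dict(zip(groups, [1.0, 2.0, 0.5, 3.0]))
    mus = dict(zip(groups, [0.0, 1.0, 2.0, 3.0]))
    g = np.repeat(groups, args.n_per_group)
    y = np.array([rng.normal(mus[x], sds[x]) for x in g])
    d = pd.DataFrame({"response": y, "grp": g})

    with tempfile.TemporaryDirectory() as tmp:
        csv = Path(tmp) / "fixture.csv"
        d.to_csv(csv, index=False)
        script = Path(tmp) / "ref.R"
        script.write_text(R_CODE.format(csv=csv))
        proc = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        if proc.returncode != 0:
            print(proc.stderr, file=sys.stderr)
            return 1
        ref = json.loads(proc.stdout)

    worst = 0.0
    for method in ("ML", "REML"):
        f = fit(ModelSpec("response", ("grp",), "grp", method), d)
        r = ref[method]
        mine_ratios = [f.variance_ratios[x] for x in groups]
        mine_se = [c.se for c in f.coefficients.values()]
        checks = {
            "logLik": (f.logLik, r["logLik"]),
            "AIC": (f.AIC, r["AIC"]),
            "beta": (f.beta, np.asarray(r["beta"])),
            "sigma": (f.sigma_ref, r["sigma"]),
            "ratios": (np.asarray(mine_ratios), np.asarray(r["ratios"])),
            "se": (np.asarray(mine_se), np.asarray(r["se"])),
        }
        print(f"\n== {method} ==")
        for name, (mine, theirs) in checks.items():
            dev = float(np.max(np.abs(np.asarray(mine) - np.asarray(theirs))))
            worst = max(worst, dev)
            print(f"  {name:7s} max |diff| = {dev:.2e}")
    ok = worst < 1e-4
    print(f"\nworst deviation {worst:.2e} -> {'OK (< 1e-4)' if ok else 'MISMATCH'}")
    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
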