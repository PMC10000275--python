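"""Regenerate the frozen TMM and ComBat oracle fixtures under tests/data/.

The fixtures hold the output of independent reference implementations
(edgeR's calcNormFactors and sva's ComBat, run through Rscript) on small
seeded inputs that the test suite re-creates deterministically in numpy.
Run from the repository root:

    python scripts/make_oracle_fixtures.py
"""

import json
import subprocess
import tempfile
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "tests" / "data"


def tmm_input(seed: int = 101, n_genes: int = 200, n_samples: int = 10) -> np.ndarray:
    """Seeded NB-like count matrix; must match tests/test_preprocess.py exactly."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=3.0, sigma=1.2, size=n_genes)
    depth = rng.lognormal(mean=0.0, sigma=0.35, size=n_samples)
    mu = np.outer(base, depth)
    lam = rng.gamma(shape=5.0, scale=mu / 5.0)
    return rng.poisson(lam).astype(float)


def combat_input(seed: int = 202, n_genes: int = 60, n_samples: int = 20):
    """Seeded two-batch matrix with location/scale effects; mirrored in tests."""
    rng = np.random.default_rng(seed)
    batch = np.array([0] * 12 + [1] * 8)
    mu = rng.normal(5.0, 2.0, size=n_genes)
    shift = rng.normal(0.0, 1.0, size=n_genes)
    scale = rng.uniform(0.6, 1.8, size=n_genes)
    y = mu[:, None] + rng.normal(size=(n_genes, n_samples))
    y[:, batch == 1] = (
        mu[:, None]
        + shift[:, None]
        + scale[:, None] * rng.normal(size=(n_genes, (batch == 1).sum()))
    )
    return y, batch


def run_r(script: str) -> str:
    res = subprocess.run(
        ["Rscript", "--vanilla", "-e", script], capture_output=True, text=True, check=True
    )
    return res.stdout


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp())

    counts = tmm_input()
    np.savetxt(tmp / "counts.tsv", counts, delimiter="\t", fmt="%.1f")
    r = f"""
suppressMessages(library(edgeR))
x <- as.matrix(read.delim("{tmp}/counts.tsv", header=FALSE))
f <- calcNormFactors(x, method="TMM")
cat(toJSON <- paste0("[", paste(sprintf("%.12g", f), collapse=","), "]"))
"""
    factors = json.loads(run_r(r))
    (OUT / "tmm_oracle.json").write_text(
        json.dumps(
            {
                "description": "edgeR 4.0 calcNormFactors(method='TMM') on tmm_input(seed=101)",
                "seed": 101,
                "n_genes": 200,
                "n_samples": 10,
                "factors": factors,
            },
            indent=1,
        )
    )

    y, batch = combat_input()
    np.savetxt(tmp / "expr.tsv", y, delimiter="\t", fmt="%.12g")
    r = f"""
suppressMessages(library(sva))
y <- as.matrix(read.delim("{tmp}/expr.tsv", header=FALSE))
batch <- c(rep(1, 12), rep(2, 8))
out <- ComBat(dat=y, batch=batch, par.prior=TRUE, prior.plots=FALSE)
write.table(format(out, digits=15), "{tmp}/combat_out.tsv", sep="\t",
            row.names=FALSE, col.names=FALSE, quote=FALSE)
"""
    run_r(r)
    corrected = np.loadtxt(tmp / "combat_out.tsv")
    (OUT / "combat_oracle.json").write_text(
        json.dumps(
            {
                "description": "sva 3.50 ComBat(par.prior=TRUE) on combat_input(seed=202)",
                "seed": 202,
                "n_genes": 60,
                "n_samples": 20,
                "batch": batch.tolist(),
                "corrected": [[round(v, 10) for v in row] for row in corrected.tolist()],
            },
            indent=None,
        )
    )
    print("wrote", OUT / "tmm_oracle.json", "and", OUT / "combat_oracle.json")


if __name__ == "__main__":
    main()
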