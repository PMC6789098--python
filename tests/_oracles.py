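"""Independent R oracles (edgeR, limma, MASS) run through Rscript.

One Rscript invocation computes every reference quantity on tiny fixtures
and writes a JSON blob; tests compare the native implementations against
it.  The fixtures are generated in Python and passed as TSV.
"""

import json
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

R_SCRIPT = r"""
suppressMessages({library(edgeR); library(limma); library(MASS); library(jsonlite)})
args <- commandArgs(trailingOnly = TRUE)
dir <- args[1]
out <- list()

counts <- as.matrix(read.delim(file.path(dir, "counts.tsv"), row.names = 1))
f <- calcNormFactors(counts, method = "TMM")
lib <- colSums(counts)
eff <- lib * f
out$tmm_effective <- as.numeric(eff / exp(mean(log(eff))))

y <- as.matrix(read.delim(file.path(dir, "logcpm.tsv"), row.names = 1))
group <- scan(file.path(dir, "group.txt"), quiet = TRUE)
design <- cbind(1, group)
fit <- eBayes(lmFit(y, design), trend = TRUE)
out$limma_t <- as.numeric(fit$t[, 2])
out$limma_p <- as.numeric(fit$p.value[, 2])
out$limma_d0 <- fit$df.prior

d <- scan(file.path(dir, "diffs.txt"), quiet = TRUE)
rfit <- rlm(d ~ 1, k = 1.345, maxit = 50)
out$rlm_intercept <- as.numeric(coef(rfit)[1])

write(toJSON(out, digits = 12, auto_unbox = TRUE), file.path(dir, "oracle.json"))
"""


def run_r_oracles(counts: np.ndarray, logcpm: np.ndarray, group: np.ndarray,
                  diffs: np.ndarray) -> dict:
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        pd.DataFrame(counts, index=[f"g{i}" for i in range(counts.shape[0])]
                     ).to_csv(tmp / "counts.tsv", sep="\t")
        pd.DataFrame(logcpm, index=[f"g{i}" for i in range(logcpm.shape[0])]
                     ).to_csv(tmp / "logcpm.tsv", sep="\t")
        np.savetxt(tmp / "group.txt", group, fmt="%d")
        np.savetxt(tmp / "diffs.txt", diffs)
        script = tmp / "oracle.R"
        script.write_text(R_SCRIPT)
        subprocess.run(["Rscript", str(script), str(tmp)], check=True,
                       capture_output=True, timeout=300)
        return json.loads((tmp / "oracle.json").read_text())
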