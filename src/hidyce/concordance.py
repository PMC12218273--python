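"""Cross-assay VAF concordance and the dPCR droplet decision rule.

The packaged clinical fixture (``data/table1.tsv``) holds per-patient
KRAS calls from four assays on fine-needle-biopsy DNA: the high-dynamic-
range CE at 10 ng and 2 ng input, targeted amplicon sequencing, and
droplet digital PCR.  Concordance between two assays is the Pearson
correlation of paired VAFs with the coding convention:

* ND ("not detected": the assay ran and saw no mutant signal) counts
  as VAF 0, so double-negatives contribute a (0, 0) pair;
* N/A ("not analyzed": the assay was not performed) excludes the row.

Patients carrying two mutations contribute one pair per mutation.  A few
fixture cells are typographically ambiguous in the source table; they
are marked in the ``ambiguous`` column and
:func:`table1_report` quantifies the sensitivity of r to their coding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

METHODS = ("hidy10", "ampseq", "hidy2", "dpcr")

#: Minimum mutant-positive droplet count for a dPCR mutation call.
DPCR_MIN_MT_DROPLETS = 4


@dataclass(frozen=True)
class PearsonResult:
    r: float
    slope: float
    intercept: float
    n_pairs: int


@dataclass(frozen=True)
class DropletCount:
    mt_droplets: int
    wt_droplets: int
    total_droplets: int

    def __post_init__(self) -> None:
        if min(self.mt_droplets, self.wt_droplets, self.total_droplets) < 0:
            raise ValueError("droplet counts must be nonnegative")
        if self.mt_droplets + self.wt_droplets > self.total_droplets:
            raise ValueError("mt + wt droplets exceed total")


@dataclass(frozen=True)
class DpcrCall:
    detected: bool
    vaf_percent: float
    reference_only: bool


def load_table1(path=None) -> pd.DataFrame:
    """Load the clinical assay table (packaged fixture by default)."""
    if path is None:
        ref = resources.files("hidyce").joinpath("data/table1.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"patient"} | {f"{m}_mut" for m in METHODS} | {
        f"{m}_vaf" for m in METHODS
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    return df.fillna("")


def _cell_value(mut: str, vaf: str, row_id: str) -> float | None:
    """Numeric VAF, 0.0 for ND, None for N/A; rejects malformed tokens."""
    mut = mut.strip().rstrip("*")
    if mut == "N/A":
        return None
    if mut == "ND":
        return 0.0
    try:
        return float(vaf)
    except ValueError:
        raise ValueError(
            f"row {row_id}: malformed VAF token {vaf!r} for call {mut!r}"
        ) from None


def pair_table(
    table: pd.DataFrame, method_a: str = "hidy10", method_b: str = "ampseq"
) -> np.ndarray:
    """Extract numeric VAF pairs for two assays under the coding rules."""
    for m in (method_a, method_b):
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
    pairs = []
    for _, row in table.iterrows():
        rid = f"patient {row['patient']}"
        a = _cell_value(row[f"{method_a}_mut"], row[f"{method_a}_vaf"], rid)
        b = _cell_value(row[f"{method_b}_mut"], row[f"{method_b}_vaf"], rid)
        if a is None or b is None:
            continue
        pairs.append((a, b))
    return np.asarray(pairs, dtype=float).reshape(-1, 2)


def pearson(pairs: np.ndarray) -> PearsonResult:
    """Sample Pearson r plus the least-squares best-fit line."""
    pairs = np.asarray(pairs, dtype=float).reshape(-1, 2)
    if pairs.shape[0] < 3:
        raise ValueError("need at least 3 pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one coordinate")
    fit = stats.linregress(x, y)
    return PearsonResult(
        r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_pairs=pairs.shape[0],
    )


def dpcr_call(d: DropletCount) -> DpcrCall:
    """Apply the droplet-count decision rule with Poisson occupancy VAF.

    A sample harbours the mutation only when more than three droplets
    are mutant-positive; at three or fewer, the VAF is still computed
    but returned as a reference value.  Concentrations use the Poisson
    occupancy correction lambda = -ln(1 - positives/total).
    """
    if d.total_droplets <= 0:
        raise ValueError("total_droplets must be positive")
    for positives, label in ((d.mt_droplets, "MT"), (d.wt_droplets, "WT")):
        if positives == d.total_droplets:
            raise ValueError(
                f"all droplets {label}-positive: occupancy undefined"
            )
    lam_mt = -math.log(1.0 - d.mt_droplets / d.total_droplets)
    lam_wt = -math.log(1.0 - d.wt_droplets / d.total_droplets)
    if lam_mt + lam_wt == 0:
        raise ValueError("no positive droplets on either channel")
    detected = d.mt_droplets >= DPCR_MIN_MT_DROPLETS
    return DpcrCall(
        detected=detected,
        vaf_percent=100.0 * lam_mt / (lam_mt + lam_wt),
        reference_only=not detected,
    )


def table1_report(table: pd.DataFrame | None = None) -> dict:
    """Concordance report with ambiguity sensitivity.

    Computes r for the 10 ng HiDy vs amplicon-sequencing comparison and
    the 2 ng HiDy vs dPCR comparison, then recomputes each r with every
    typographically ambiguous cell recoded from ND to N/A (row dropped)
    to show how little the correlations depend on those cells.
    """
    if table is None:
        table = load_table1()
    comparisons = {"hidy10_vs_ampseq": ("hidy10", "ampseq"),
                   "hidy2_vs_dpcr": ("hidy2", "dpcr")}
    report: dict = {}
    for key, (a, b) in comparisons.items():
        res = pearson(pair_table(table, a, b))
        report[key] = {
            "r": res.r, "slope": res.slope,
            "intercept": res.intercept, "n_pairs": res.n_pairs,
        }
    sensitivity = {}
    if "ambiguous" in table.columns:
        flagged = table[table["ambiguous"].str.strip() != ""]
        for idx, row in flagged.iterrows():
            alt = table.copy()
            for m in row["ambiguous"].split(","):
                m = m.strip()
                alt.loc[idx, f"{m}_mut"] = "N/A"
                alt.loc[idx, f"{m}_vaf"] = "-"
            for key, (a, b) in comparisons.items():
                r_alt = pearson(pair_table(alt, a, b)).r
                sensitivity.setdefault(key, {})[
                    f"patient_{row['patient']}_as_NA"
                ] = r_alt
    report["ambiguity_sensitivity"] = sensitivity
    return report
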