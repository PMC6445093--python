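"""Multi-cohort differential selection of progression-related plasma proteins.

Two analyses run on the peptide-level cohort tables:

1. *Per-cohort candidates* — within each cohort, proteins identified by
   several peptides are tested with a paired t-test across their
   peptides (M vs non-M pooled runs, log2 scale) at p < 0.05;
   single-peptide proteins are kept only when the peptide maps uniquely
   and its identification score is at least 6.0 (natural-log likelihood),
   and are then selected on fold change alone.  A candidate additionally
   needs a fold change strictly beyond 1.25 in either direction.

2. *Four-cohort concordance* — on loess-normalized protein-level log2
   data, a protein is a concordant progression protein when its M/non-M
   fold change exceeds 1.25 (strictly) in the same direction in at least
   3 of the 4 cohorts, no cohort crosses the threshold in the opposite
   direction, and a paired t-test across the four cohort-level (M,
   non-M) pairs gives p < 0.1.

The two analyses are deliberately not chained: the concordance rule is a
fresh pass over the full normalized protein table, which is how the
selection reaches useful sensitivity with 2-5 peptides per protein.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

REQUIRED_PEPTIDE_COLUMNS = (
    "peptide_id", "protein_symbol", "n_mapped_proteins", "peptide_score",
    "abundance_M", "abundance_nonM",
)

#: smallest representable two-sided p, reported for degenerate zero-variance
#: tests with a nonzero mean difference
P_DEGENERATE = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class PairedTResult:
    statistic: float
    pvalue: float
    df: int
    degenerate: bool = False

    @property
    def significant_at(self):
        """p-threshold comparator honouring the degenerate flag."""
        return lambda alpha: self.degenerate or self.pvalue < alpha


def paired_t(values_a, values_b) -> PairedTResult:
    """Paired two-sided Student t-test: t = mean(d) / (sd(d)/sqrt(n)).

    Degenerate inputs follow the selection-rule contract: all
    differences exactly zero gives (t=0, p=1); zero variance with a
    nonzero mean difference is flagged degenerate and reported at the
    smallest representable p (the evidence is unbounded).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_t expects two 1-d arrays of equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    if np.all(d == 0):
        return PairedTResult(0.0, 1.0, n - 1)
    sd = d.std(ddof=1)
    mean = d.mean()
    # zero variance up to rounding noise in the differences
    if sd <= 1e-10 * abs(mean):
        sd = 0.0
    if sd == 0:
        return PairedTResult(math.copysign(math.inf, mean), P_DEGENERATE,
                             n - 1, degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return PairedTResult(float(t), float(p), n - 1)


# ---------------------------------------------------------------------------
# loess normalization
# ---------------------------------------------------------------------------

def loess_normalize(table: pd.DataFrame, span: float = 0.3,
                    log_input: bool = False) -> pd.DataFrame:
    """Remove smooth abundance-dependent bias per sample (loess, log2 scale).

    ``table`` is protein x sample.  Each column's deviation from the
    row-wise median reference profile is smoothed against the reference
    abundance (M-vs-A style) and subtracted; columns are then re-centred
    so each sample's median equals the reference median.  Input is linear
    abundance unless ``log_input`` is set; output is always log2.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must lie in (0, 1], got {span}")
    if len(table) < 10:
        raise ValueError("need at least 10 proteins for loess normalization")
    if log_input:
        log = table.astype(float)
    else:
        bad = table.le(0).any(axis=1)
        if bad.any():
            raise ValueError(
                f"non-positive abundance in rows: {list(table.index[bad])[:5]}")
        log = np.log2(table.astype(float))
    ref = log.median(axis=1)
    ref_median = float(ref.median())
    out = pd.DataFrame(index=log.index, columns=log.columns, dtype=float)
    for col in log.columns:
        mask = log[col].notna() & ref.notna()
        x = ref[mask].to_numpy()
        m = (log[col][mask] - ref[mask]).to_numpy()
        fitted = lowess(m, x, frac=span, return_sorted=False)
        norm = log[col][mask] - fitted
        norm = norm + (ref_median - float(np.median(norm)))
        out.loc[mask, col] = norm
    return out


# ---------------------------------------------------------------------------
# per-cohort candidate selection
# ---------------------------------------------------------------------------

def per_cohort_candidates(cohort: pd.DataFrame, fc_cutoff: float = 1.25,
                          p_cutoff: float = 0.05, score_cutoff: float = 6.0,
                          agg: str = "mean") -> pd.DataFrame:
    """Per-protein differential statistics and candidacy within one cohort.

    Returns a frame indexed by protein with columns ``n_peptides, fc, p,
    degenerate, candidate, direction, reason``.  Protein fold change is
    the ratio of peptide-abundance means (``agg='median'`` selectable);
    the paired test runs on log2 peptide abundances.  Exclusion reasons:
    ``multi_mapped`` / ``low_score`` for unreliable single-peptide
    identifications, empty string otherwise.
    """
    missing = [c for c in REQUIRED_PEPTIDE_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if agg not in ("mean", "median"):
        raise ValueError("agg must be 'mean' or 'median'")
    if (cohort[["abundance_M", "abundance_nonM"]] <= 0).any().any():
        raise ValueError("peptide abundances must be strictly positive")
    agg_fn = np.mean if agg == "mean" else np.median
    rows = []
    for symbol, grp in cohort.groupby("protein_symbol", sort=True):
        n = len(grp)
        m = grp["abundance_M"].to_numpy(dtype=float)
        nm = grp["abundance_nonM"].to_numpy(dtype=float)
        fc = float(agg_fn(m) / agg_fn(nm))
        p = np.nan
        degenerate = False
        reason = ""
        if n == 1:
            row = grp.iloc[0]
            if int(row["n_mapped_proteins"]) > 1:
                reason = "multi_mapped"
            elif float(row["peptide_score"]) < score_cutoff:
                reason = "low_score"
            p_ok = reason == ""
        else:
            res = paired_t(np.log2(m), np.log2(nm))
            p, degenerate = res.pvalue, res.degenerate
            p_ok = degenerate or p < p_cutoff
        fc_ok = fc > fc_cutoff or fc < 1.0 / fc_cutoff
        candidate = bool(p_ok and fc_ok and not reason)
        direction = ("up" if fc > fc_cutoff else
                     "down" if fc < 1.0 / fc_cutoff else "none") if candidate else "none"
        rows.append({"protein_symbol": symbol, "n_peptides": n, "fc": fc,
                     "p": p, "degenerate": degenerate, "candidate": candidate,
                     "direction": direction, "reason": reason})
    out = pd.DataFrame(rows).set_index("protein_symbol")
    n_excluded = int((out["reason"] != "").sum())
    if n_excluded:
        logger.info("excluded %d unreliable single-peptide proteins", n_excluded)
    return out


def protein_table(cohorts: Mapping[str, pd.DataFrame], score_cutoff: float = 6.0,
                  agg: str = "mean") -> pd.DataFrame:
    """Protein-level abundance table across cohorts (linear scale).

    Columns are a (cohort, channel) MultiIndex with channels ``M`` and
    ``nonM``; values are peptide-abundance means.  Single-peptide
    proteins failing the mapping-uniqueness or score rule are dropped
    per cohort (NaN), mirroring the per-cohort reliability filter.
    """
    agg_fn = "mean" if agg == "mean" else "median"
    pieces = {}
    for cid, df in cohorts.items():
        counts = df.groupby("protein_symbol")["peptide_id"].transform("size")
        reliable = (counts > 1) | ((df["n_mapped_proteins"] == 1)
                                   & (df["peptide_score"] >= score_cutoff))
        sub = df[reliable]
        g = sub.groupby("protein_symbol")[["abundance_M", "abundance_nonM"]]
        prot = g.agg(agg_fn)
        # proteins whose only peptides were filtered stay as NaN rows
        all_symbols = pd.Index(sorted(df["protein_symbol"].unique()))
        prot = prot.reindex(all_symbols)
        pieces[(cid, "M")] = prot["abundance_M"]
        pieces[(cid, "nonM")] = prot["abundance_nonM"]
    out = pd.DataFrame(pieces)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["cohort", "channel"])
    return out


# ---------------------------------------------------------------------------
# four-cohort concordance
# ---------------------------------------------------------------------------

def concordant_progression_proteins(
    proteins: pd.DataFrame,
    fc_cutoff: float = 1.25,
    min_cohorts: int = 3,
    combined_p_cutoff: float = 0.1,
    normalize: bool = True,
    span: float = 0.3,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Concordance filter over the per-cohort protein table.

    ``proteins`` is the output of :func:`protein_table` (linear
    abundances).  With ``normalize`` (default) the 2 x n_cohorts sample
    columns are loess-normalized jointly before fold changes and the
    cross-cohort paired t-test are computed.  A protein is reported
    ``up`` when strictly more than ``fc_cutoff`` in >= ``min_cohorts``
    cohorts, no cohort crosses the reciprocal threshold (opposite-
    direction veto), and the cross-cohort paired t over the per-cohort
    (M, non-M) log2 values satisfies p < ``combined_p_cutoff`` (a
    degenerate zero-variance/nonzero-mean test counts as significant);
    symmetrically for ``down``.  ``adjust='bh'`` applies
    Benjamini-Hochberg to the combined p-values first (off by default,
    as in the original selection).

    Returns a frame indexed by protein with per-cohort ``fc_<cohort>``
    columns, ``combined_p``, ``degenerate``, ``n_concordant`` and
    ``direction`` (up/down/none).
    """
    if not isinstance(proteins.columns, pd.MultiIndex):
        raise ValueError("proteins must have (cohort, channel) MultiIndex columns")
    cohort_ids = list(proteins.columns.get_level_values("cohort").unique())
    if normalize:
        flat = proteins.copy()
        flat.columns = [f"{c}|{ch}" for c, ch in proteins.columns]
        norm = loess_normalize(flat, span=span)
        norm.columns = proteins.columns
        log = norm
    else:
        if (proteins.le(0)).any().any():
            raise ValueError("protein abundances must be strictly positive")
        log = np.log2(proteins.astype(float))

    logfc = pd.DataFrame({c: log[(c, "M")] - log[(c, "nonM")] for c in cohort_ids})
    if normalize:
        fc = np.exp2(logfc)
    else:
        # linear ratio straight from the input so threshold boundaries
        # (e.g. exactly 1.25) are not blurred by the log round trip
        fc = pd.DataFrame({c: proteins[(c, "M")] / proteins[(c, "nonM")]
                           for c in cohort_ids})
    n_up = (fc > fc_cutoff).sum(axis=1)
    n_down = (fc < 1.0 / fc_cutoff).sum(axis=1)
    n_obs = logfc.notna().sum(axis=1)
    if (n_obs < len(cohort_ids)).any():
        logger.info("%d proteins missing in >=1 cohort treated as non-concordant",
                    int((n_obs < len(cohort_ids)).sum()))

    # cross-cohort paired t over available (M, nonM) pairs
    d = logfc.to_numpy()
    import warnings as _warnings
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN rows
        mean = np.nanmean(d, axis=1)
        sd = np.nanstd(d, axis=1, ddof=1)
    valid = n_obs.to_numpy() >= 2
    zero_sd = sd <= 1e-10 * np.abs(mean)   # rounding-tolerant, as in paired_t
    t = np.full(len(logfc), np.nan)
    p = np.full(len(logfc), np.nan)
    nz = valid & ~zero_sd
    t[nz] = mean[nz] / (sd[nz] / np.sqrt(n_obs.to_numpy()[nz]))
    p[nz] = 2.0 * stats.t.sf(np.abs(t[nz]), n_obs.to_numpy()[nz] - 1)
    degenerate = valid & zero_sd & (mean != 0)
    p[degenerate] = P_DEGENERATE
    p[valid & zero_sd & (mean == 0)] = 1.0

    p_for_rule = p.copy()
    if adjust == "bh":
        ok = np.isfinite(p_for_rule)
        p_for_rule[ok] = multipletests(p_for_rule[ok], method="fdr_bh")[1]
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")

    p_ok = degenerate | (p_for_rule < combined_p_cutoff)
    up = (n_up >= min_cohorts) & (n_down == 0) & p_ok
    down = (n_down >= min_cohorts) & (n_up == 0) & p_ok
    direction = np.where(up, "up", np.where(down, "down", "none"))

    out = pd.DataFrame(index=proteins.index)
    for c in cohort_ids:
        out[f"fc_{c}"] = fc[c]
    out["combined_p"] = p
    if adjust == "bh":
        out["combined_q"] = p_for_rule
    out["degenerate"] = degenerate
    out["n_concordant"] = np.where(up, n_up, np.where(down, n_down, 0)).astype(int)
    out["direction"] = direction
    out.index.name = "protein_symbol"
    return out


def up_down_sets(concordant: pd.DataFrame) -> tuple[set[str], set[str]]:
    """(up, down) symbol sets from a concordance table."""
    return (set(concordant.index[concordant["direction"] == "up"]),
            set(concordant.index[concordant["direction"] == "down"]))


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    """Both selection stages of the differential analysis."""

    per_cohort: dict[str, pd.DataFrame]
    concordant: pd.DataFrame

    @property
    def up(self) -> set[str]:
        return up_down_sets(self.concordant)[0]

    @property
    def down(self) -> set[str]:
        return up_down_sets(self.concordant)[1]


def differential_analysis(cohorts: Mapping[str, pd.DataFrame],
                          fc_cutoff: float = 1.25, p_single: float = 0.05,
                          p_combined: float = 0.1, min_cohorts: int = 3,
                          score_cutoff: float = 6.0, span: float = 0.3,
                          normalize: bool = True, agg: str = "mean",
                          adjust: str | None = None) -> DifferentialResult:
    """Run both selection stages on the four cohort peptide tables."""
    per_cohort = {cid: per_cohort_candidates(df, fc_cutoff=fc_cutoff,
                                             p_cutoff=p_single,
                                             score_cutoff=score_cutoff, agg=agg)
                  for cid, df in cohorts.items()}
    prot = protein_table(cohorts, score_cutoff=score_cutoff, agg=agg)
    conc = concordant_progression_proteins(prot, fc_cutoff=fc_cutoff,
                                           min_cohorts=min_cohorts,
                                           combined_p_cutoff=p_combined,
                                           normalize=normalize, span=span,
                                           adjust=adjust)
    return DifferentialResult(per_cohort=per_cohort, concordant=conc)
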