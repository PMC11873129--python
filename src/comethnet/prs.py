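"""Polygenic risk scoring with module-window refinement, and survival models.

Implements clumping + thresholding (C+T) polygenic scores from GWAS summary
statistics and cohort dosages; a *refined* score restricts the variant set
to ±1 Mb windows around the trait module's CpG coordinates (the usual span
of local methylation quantitative trait loci). Scores are tested against a
binary depression outcome (incremental R² over sex + 3 genetic principal
components, BH-FDR across the score-set × threshold family) and against
longitudinal conversion to depression via a counting-process Cox model with
sex fixed and age / motor score (UPDRS-III) time-dependent, plus
Kaplan-Meier strata of polygenic risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from comethnet.stats import bh_adjust

__all__ = [
    "PRS_THRESHOLDS",
    "HarmonizeReport",
    "harmonize_sumstats",
    "ld_clump",
    "module_windows",
    "compute_prs",
    "genetic_pcs",
    "prs_trait_r2",
    "build_event_table",
    "cox_time_dependent",
    "km_percentile_strata",
]

#: the standard C+T p-value threshold ladder
PRS_THRESHOLDS = (1.0, 0.5, 0.05, 0.005, 5e-4, 5e-5, 5e-6, 5e-7, 5e-8)

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class HarmonizeReport:
    n_input: int
    n_info_dropped: int
    n_ambiguous_dropped: int
    n_flipped: int
    n_unresolved_dropped: int


def harmonize_sumstats(
    raw: pd.DataFrame,
    panel_alleles: pd.DataFrame | None = None,
    info_min: float = 0.9,
) -> tuple[pd.DataFrame, HarmonizeReport]:
    """Filter and allele-align GWAS summary statistics.

    Drops variants with INFO < ``info_min`` and strand-ambiguous (A/T, C/G)
    variants. If ``panel_alleles`` (columns SNP, counted, other) is given,
    effect sizes are flipped where the panel counts the other allele;
    irreconcilable allele pairs are dropped and reported.
    """
    ss = raw.copy()
    n_input = len(ss)
    ss = ss[ss["INFO"] >= info_min]
    n_info = n_input - len(ss)
    amb = ss.apply(lambda r: frozenset((r["A1"], r["A2"])) in _AMBIGUOUS, axis=1)
    n_amb = int(amb.sum())
    ss = ss[~amb]
    n_flip = 0
    n_unres = 0
    if panel_alleles is not None:
        panel = panel_alleles.set_index("SNP")
        keep_rows = []
        for _, row in ss.iterrows():
            snp = row["SNP"]
            if snp not in panel.index:
                keep_rows.append(row)
                continue
            counted, other = panel.loc[snp, "counted"], panel.loc[snp, "other"]
            if (row["A1"], row["A2"]) == (counted, other):
                keep_rows.append(row)
            elif (row["A1"], row["A2"]) == (other, counted):
                row = row.copy()
                row["BETA"] = -row["BETA"]
                row["A1"], row["A2"] = counted, other
                keep_rows.append(row)
                n_flip += 1
            else:
                # try strand complement
                ca1, ca2 = _COMPLEMENT[row["A1"]], _COMPLEMENT[row["A2"]]
                if (ca1, ca2) == (counted, other):
                    row = row.copy()
                    row["A1"], row["A2"] = counted, other
                    keep_rows.append(row)
                elif (ca2, ca1) == (counted, other):
                    row = row.copy()
                    row["BETA"] = -row["BETA"]
                    row["A1"], row["A2"] = counted, other
                    keep_rows.append(row)
                    n_flip += 1
                else:
                    n_unres += 1
        ss = pd.DataFrame(keep_rows, columns=ss.columns).reset_index(drop=True)
    report = HarmonizeReport(n_input, n_info, n_amb, n_flip, n_unres)
    return ss.reset_index(drop=True), report


def ld_clump(
    ss: pd.DataFrame,
    geno: pd.DataFrame,
    r2_max: float = 0.1,
    window_kb: float = 1000.0,
) -> list[str]:
    """Greedy LD clumping: best-p index variants, neighbours above r² removed.

    Variants are visited by ascending p (ties: smaller bp, then id); each
    index variant removes every unclumped variant within ``window_kb`` whose
    dosage r² with it exceeds ``r2_max``. Deterministic and independent of
    input row order.
    """
    shared = ss[ss["SNP"].isin(geno.columns)]
    if shared.empty:
        raise ValueError("no overlap between summary statistics and genotypes")
    shared = shared.sort_values(["P", "BP", "SNP"], kind="mergesort")
    snps = shared["SNP"].to_numpy()
    bps = shared.set_index("SNP")["BP"]
    chrom = shared.set_index("SNP")["CHR"]
    X = geno[snps].to_numpy(float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = np.inf
    X = X / sd
    pos = {s: i for i, s in enumerate(snps)}
    window = window_kb * 1000.0
    alive = dict.fromkeys(snps, True)
    index_set: list[str] = []
    n = len(X)
    for s in snps:
        if not alive[s]:
            continue
        index_set.append(s)
        alive[s] = False
        near = [
            t
            for t in snps
            if alive[t]
            and chrom[t] == chrom[s]
            and abs(bps[t] - bps[s]) <= window
        ]
        if near:
            xi = X[:, pos[s]]
            r = X[:, [pos[t] for t in near]].T @ xi / n
            for t, rv in zip(near, r):
                if rv**2 > r2_max:
                    alive[t] = False
    return index_set


def module_windows(
    probes: set[str], annotation: pd.DataFrame, flank_bp: int = 1_000_000
) -> pd.DataFrame:
    """Merged ±``flank_bp`` genomic windows around the module's CpG sites.

    Returns a frame (chr, start, end), half-open 0-based, sorted and
    non-overlapping. Probes without coordinates are skipped and counted in
    ``attrs['n_skipped']``.
    """
    ann = annotation.set_index("probe")
    skipped = 0
    raw: list[tuple[str, int, int]] = []
    for p in sorted(probes):
        if p not in ann.index or pd.isna(ann.loc[p, "pos"]):
            skipped += 1
            continue
        c, pos = ann.loc[p, "chr"], int(ann.loc[p, "pos"])
        raw.append((c, max(0, pos - flank_bp), pos + flank_bp))
    merged: list[list] = []
    for c, s, e in sorted(raw):
        if merged and merged[-1][0] == c and s <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], e)
        else:
            merged.append([c, s, e])
    out = pd.DataFrame(merged, columns=["chr", "start", "end"])
    out.attrs["n_skipped"] = skipped
    return out


def _in_windows(chrom: pd.Series, bp: pd.Series, windows: pd.DataFrame) -> np.ndarray:
    mask = np.zeros(len(bp), dtype=bool)
    ch = chrom.astype(str).to_numpy()
    ch = np.char.add("chr", np.char.lstrip(ch.astype(str), "chr"))
    b = bp.to_numpy(int)
    for _, w in windows.iterrows():
        mask |= (ch == str(w["chr"])) & (b >= w["start"]) & (b < w["end"])
    return mask


def compute_prs(
    geno: pd.DataFrame,
    ss: pd.DataFrame,
    index_set: list[str],
    thresholds: tuple[float, ...] = PRS_THRESHOLDS,
    restrict: pd.DataFrame | None = None,
    average: bool = True,
) -> pd.DataFrame:
    """Clumping + thresholding scores per p-value threshold.

    score = sum(dosage * beta) / (2 * n_variants) when ``average`` (the
    per-allele average), else the raw sum. Missing dosages are mean-imputed
    per variant. ``restrict`` (a window frame from :func:`module_windows`)
    intersects the variant set — the refined score. Thresholds with no
    variants yield NaN columns, recorded in ``attrs['empty_thresholds']``.
    """
    ss = ss[ss["SNP"].isin(index_set) & ss["SNP"].isin(geno.columns)]
    if restrict is not None:
        ss = ss[_in_windows(ss["CHR"], ss["BP"], restrict)]
    scores = {}
    n_variants = {}
    empty = []
    for t in sorted(thresholds, reverse=True):
        sub = ss[ss["P"] <= t]
        n_variants[t] = len(sub)
        if sub.empty:
            empty.append(t)
            scores[t] = pd.Series(np.nan, index=geno.index)
            continue
        X = geno[sub["SNP"]].to_numpy(float)
        if np.isnan(X).any():
            col_mean = np.nanmean(X, axis=0)
            X = np.where(np.isnan(X), col_mean[None, :], X)
        b = sub["BETA"].to_numpy(float)
        s = X @ b
        if average:
            s = s / (2 * len(sub))
        scores[t] = pd.Series(s, index=geno.index)
    if len(empty) == len(thresholds):
        raise ValueError("no variants pass any threshold")
    if empty:
        warnings.warn(f"thresholds with zero variants: {empty}")
    out = pd.DataFrame(scores)
    out = out[list(thresholds)]
    out.attrs["n_variants"] = n_variants
    out.attrs["empty_thresholds"] = empty
    return out


def genetic_pcs(geno: pd.DataFrame, n_pcs: int = 3) -> pd.DataFrame:
    """Top principal components of the centred dosage matrix."""
    X = geno.to_numpy(float)
    X = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    pcs = U[:, :n_pcs] * s[:n_pcs]
    return pd.DataFrame(
        pcs, index=geno.index, columns=[f"PC{i + 1}" for i in range(n_pcs)]
    )


def prs_trait_r2(
    scores_by_set: dict[str, pd.DataFrame],
    outcome: pd.Series,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Incremental R² of each (score set, threshold) over the covariates.

    A linear model of the binary outcome on covariates + PRS; incremental
    R² = R²(full) − R²(covariates only); p is the Wald test on the PRS
    coefficient; BH-FDR is applied jointly across every test in the family.
    """
    if outcome.nunique() < 2:
        raise ValueError("outcome is constant")
    rows = []
    for set_name, scores in scores_by_set.items():
        for t in scores.columns:
            s = scores[t]
            df = pd.concat(
                [outcome.rename("y"), covariates, s.rename("prs")], axis=1
            ).dropna()
            if df.empty or df["prs"].std() == 0:
                rows.append((set_name, t, scores.attrs["n_variants"].get(t, 0),
                             np.nan, np.nan))
                continue
            y = df["y"].to_numpy(float)
            C = np.column_stack([np.ones(len(df)), df[covariates.columns]])
            F = np.column_stack([C, df["prs"]])
            r2_cov = _ols_r2(C, y)
            r2_full, p_last = _ols_r2_and_p(F, y)
            rows.append(
                (set_name, t, scores.attrs["n_variants"].get(t, 0),
                 r2_full - r2_cov, p_last)
            )
    out = pd.DataFrame(
        rows, columns=["score_set", "threshold", "n_variants", "incremental_r2", "p"]
    )
    out["q"] = bh_adjust(out["p"])
    return out


def _ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = ((y - y.mean()) ** 2).sum()
    return float(1 - (resid**2).sum() / tss) if tss > 0 else 0.0

def _ols_r2_and_p(X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float((resid**2).sum())
    tss = ((y - y.mean()) ** 2).sum()
    r2 = float(1 - rss / tss) if tss > 0 else 0.0
    dof = n - k
    if dof <= 0:
        return r2, float("nan")
    sigma2 = rss / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se_last = np.sqrt(sigma2 * XtX_inv[-1, -1])
    if se_last == 0:
        return r2, float("nan")
    tstat = beta[-1] / se_last
    return r2, float(2 * sps.t.sf(abs(tstat), dof))


# ---------------------------------------------------------------------------
# time-to-event
# ---------------------------------------------------------------------------

def build_event_table(
    pheno: pd.DataFrame,
    gds_cut: int = 5,
    min_records: int = 3,
    min_event_visits: int = 2,
    event_at: str = "first",
) -> tuple[pd.DataFrame, pd.Series]:
    """Counting-process event table for conversion to depression.

    Samples need at least ``min_records`` visits; the event (confirmed
    depression) requires GDS >= ``gds_cut`` at >= ``min_event_visits``
    visits, with the event time at the first (or, with
    ``event_at='second'``, the second) qualifying visit. Unconfirmed
    samples are censored at their last visit. Covariates (age, UPDRS3) are
    carried visit-level onto each (start, stop] interval; sex is fixed.
    Samples whose event falls at the baseline visit have no time at risk
    and are excluded from the table (they still count in the binary
    outcome). Also returns the cross-sectional binary outcome: any single
    visit with GDS >= ``gds_cut``.
    """
    if event_at not in ("first", "second"):
        raise ValueError("event_at must be 'first' or 'second'")
    rows = []
    binary = {}
    for sample, g in pheno.groupby("sample", sort=True):
        g = g.reset_index(drop=True)
        months = g["visit_month"].to_numpy()
        if np.any(np.diff(months) <= 0):
            raise ValueError(f"non-monotone visit times for {sample}")
        qualifying = g.index[g["GDS"] >= gds_cut].to_numpy()
        binary[sample] = int(qualifying.size > 0)
        if len(g) < min_records:
            continue
        if qualifying.size >= min_event_visits:
            which = 0 if event_at == "first" else 1
            event_visit = int(qualifying[which])
            event_time = float(months[event_visit])
        else:
            event_visit = None
            event_time = float(months[-1])
        if event_visit == 0:
            continue  # prevalent at baseline: no time at risk
        last = event_visit if event_visit is not None else len(g) - 1
        for i in range(last):
            rows.append(
                {
                    "sample": sample,
                    "start": float(months[i]),
                    "stop": float(months[i + 1]),
                    "event": int(event_visit is not None and i + 1 == event_visit),
                    "age": float(g.loc[i, "age"]),
                    "UPDRS3": float(g.loc[i, "UPDRS3"]),
                    "sex": g.loc[i, "sex"],
                }
            )
    events = pd.DataFrame(rows)
    return events, pd.Series(binary, name="depression_ever")


def _prepare_ctv(events: pd.DataFrame, prs: pd.Series, name: str) -> pd.DataFrame:
    df = events.copy()
    df["sex"] = (df["sex"].astype(str) == "M").astype(float)
    df[name] = df["sample"].map(prs)
    df = df.dropna(subset=[name])
    sd = df.groupby("sample")[name].first().std()
    if sd and sd > 0:
        df[name] = df[name] / sd  # per-SD hazard ratios
    return df


def cox_time_dependent(
    events: pd.DataFrame, prs: pd.Series, name: str = "PRS"
) -> pd.DataFrame:
    """Counting-process Cox model of conversion on a standardised PRS.

    Sex is a fixed covariate; age and UPDRS3 enter time-dependently via the
    per-interval values. Returns a frame indexed by predictor with coef,
    HR (per SD for the PRS), SE and Wald p. Efron tie handling.
    """
    if events.empty or events["event"].sum() < 2:
        raise ValueError("need at least 2 events")
    if prs.std() == 0:
        out = pd.DataFrame(
            {"coef": [0.0], "HR": [1.0], "SE": [np.inf], "p": [1.0]},
            index=[name],
        )
        return out
    from lifelines import CoxTimeVaryingFitter

    df = _prepare_ctv(events, prs, name)
    ctv = CoxTimeVaryingFitter()
    ctv.fit(
        df[["sample", "start", "stop", "event", name, "sex", "age", "UPDRS3"]],
        id_col="sample",
        start_col="start",
        stop_col="stop",
        event_col="event",
    )
    s = ctv.summary
    out = pd.DataFrame(
        {
            "coef": s["coef"],
            "HR": np.exp(s["coef"]),
            "SE": s["se(coef)"],
            "p": s["p"],
        }
    )
    return out


def km_percentile_strata(
    events: pd.DataFrame,
    prs: pd.Series,
    strata: tuple[tuple[float, float], ...] = ((0, 5), (5, 50), (50, 95), (95, 100)),
    reference: tuple[float, float] = (5, 50),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kaplan-Meier curves and per-stratum hazard ratios by PRS percentile.

    Strata are percentile bounds covering [0, 100]; each stratum's survival
    curve uses the first-qualifying-visit event times; hazard ratios
    compare each stratum with the ``reference`` stratum in a Cox model
    adjusted for sex, age and UPDRS3. Empty strata are dropped with a
    warning.
    """
    lo = sorted(s[0] for s in strata)
    hi = sorted(s[1] for s in strata)
    if lo[0] != 0 or hi[-1] != 100:
        raise ValueError("strata must cover [0, 100]")
    from lifelines import KaplanMeierFitter

    per_sample = events.groupby("sample").agg(
        time=("stop", "max"), event=("event", "max")
    )
    prs = prs.dropna()
    shared = per_sample.index.intersection(prs.index)
    per_sample = per_sample.loc[shared]
    pr = prs.loc[shared]
    pct = pr.rank(pct=True) * 100

    curves = []
    labels = {}
    for s_lo, s_hi in strata:
        sel = (pct > s_lo) & (pct <= s_hi) if s_lo > 0 else (pct <= s_hi)
        ids = pct.index[sel]
        label = f"{s_lo:g}-{s_hi:g}%"
        if len(ids) == 0:
            warnings.warn(f"empty PRS stratum {label}; dropped")
            continue
        labels[label] = set(ids)
        km = KaplanMeierFitter()
        km.fit(
            per_sample.loc[ids, "time"],
            per_sample.loc[ids, "event"],
            label=label,
        )
        cur = km.survival_function_.reset_index()
        cur.columns = ["time", "survival"]
        cur["stratum"] = label
        cur["n"] = len(ids)
        curves.append(cur)
    curves_df = pd.concat(curves, ignore_index=True)

    ref_label = f"{reference[0]:g}-{reference[1]:g}%"
    if ref_label not in labels:
        raise ValueError(f"reference stratum {ref_label} is empty or missing")
    hr_rows = []
    from lifelines import CoxTimeVaryingFitter

    for label, ids in labels.items():
        if label == ref_label:
            continue
        pair_ids = ids | labels[ref_label]
        sub = events[events["sample"].isin(pair_ids)].copy()
        if sub["event"].sum() < 2:
            warnings.warn(f"stratum {label}: too few events for a hazard ratio")
            continue
        sub["sex"] = (sub["sex"].astype(str) == "M").astype(float)
        sub["in_stratum"] = sub["sample"].isin(ids).astype(float)
        ctv = CoxTimeVaryingFitter()
        try:
            ctv.fit(
                sub[["sample", "start", "stop", "event", "in_stratum", "sex",
                     "age", "UPDRS3"]],
                id_col="sample",
                start_col="start",
                stop_col="stop",
                event_col="event",
            )
        except Exception as exc:  # noqa: BLE001 - surfaced as a warning
            warnings.warn(f"stratum {label}: Cox fit failed ({exc})")
            continue
        s = ctv.summary.loc["in_stratum"]
        hr_rows.append(
            {
                "stratum": label,
                "reference": ref_label,
                "HR": float(np.exp(s["coef"])),
                "SE": float(s["se(coef)"]),
                "p": float(s["p"]),
            }
        )
    return curves_df, pd.DataFrame(hr_rows)
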