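"""Module-trait association, module membership and sensitivity analyses.

Module eigengenes are tested against clinical traits (Spearman for binary
traits, Pearson for continuous ones) under a per-region Bonferroni
threshold of 0.05 / number of modules. Modules still associated with any
confounding covariate (p < 0.05) are screened out *before* trait testing.
Probe-level follow-up relates module membership (probe-eigengene
correlation) to probe significance (probe-trait p-value), and a
three-group Wilcoxon analysis with BH correction supports the premorbid /
disease-stage sensitivity checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from comethnet.network import Eigengene, ModuleAssignment, GREY
from comethnet.stats import (
    bh_adjust,
    bonferroni_threshold,
    pearson_test,
    rank_sum_test,
    spearman_test,
)
from comethnet.preprocess import residualize_covariates

__all__ = [
    "ModuleTraitResult",
    "module_trait_correlations",
    "module_membership",
    "probe_significance",
    "mm_ps_relation",
    "eigengene_group_test",
]


@dataclass
class ModuleTraitResult:
    """Long-format module-trait correlation table plus screening report."""

    table: pd.DataFrame  # region?, module, trait, method, coefficient, p, ...
    bonferroni: float
    excluded_modules: pd.DataFrame  # module, confound, p


def module_trait_correlations(
    eigengenes: Eigengene,
    traits: pd.DataFrame,
    trait_types: dict[str, str],
    confounds: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> ModuleTraitResult:
    """Correlate each module eigengene with each trait.

    ``traits`` is indexed by sample with one column per trait;
    ``trait_types`` maps trait name to 'binary' (Spearman) or 'continuous'
    (Pearson). ``confounds`` (numeric, indexed by sample) screens modules
    first: any module with a confound association p < 0.05 is excluded and
    the Bonferroni threshold uses the surviving module count. Missing trait
    values are dropped pairwise per test.
    """
    me = eigengenes.scores
    shared = me.index.intersection(traits.index)
    if len(shared) < 10:
        raise ValueError("eigengenes and traits share fewer than 10 samples")
    me = me.loc[shared]

    excluded = []
    surviving = []
    for module in me.columns:
        hit = None
        if confounds is not None:
            for c in confounds.columns:
                pair = pd.concat([me[module], confounds[c]], axis=1).dropna()
                r, p = pearson_test(pair.iloc[:, 0], pair.iloc[:, 1])
                if np.isfinite(p) and p < 0.05:
                    hit = (module, c, p)
                    break
        if hit is None:
            surviving.append(module)
        else:
            excluded.append(hit)
    excluded_df = pd.DataFrame(excluded, columns=["module", "confound", "p"])
    if not surviving:
        raise ValueError("confound screening removed every module")
    threshold = bonferroni_threshold(len(surviving), alpha)

    rows = []
    for trait, kind in trait_types.items():
        t = traits.loc[shared, trait]
        for module in surviving:
            pair = pd.concat([me[module], t], axis=1).dropna()
            if pair.iloc[:, 1].nunique() < 2:
                warnings.warn(f"trait {trait} has a single level; skipped")
                continue
            if kind == "binary":
                r, p = spearman_test(pair.iloc[:, 0], pair.iloc[:, 1])
                method = "spearman"
            else:
                r, p = pearson_test(pair.iloc[:, 0], pair.iloc[:, 1])
                method = "pearson"
            rows.append(
                {
                    "module": module,
                    "trait": trait,
                    "method": method,
                    "coefficient": r,
                    "p": p,
                    "n": len(pair),
                    "bonferroni_threshold": threshold,
                    "significant": bool(p < threshold),
                }
            )
    return ModuleTraitResult(pd.DataFrame(rows), threshold, excluded_df)


def module_membership(
    beta: pd.DataFrame, eigengenes: Eigengene, assignment: ModuleAssignment
) -> pd.DataFrame:
    """MM = Pearson correlation of each probe with its own module eigengene.

    Grey probes get no MM. Returns a frame with probe, module, MM.
    """
    rows = []
    me = eigengenes.scores
    for module in assignment.modules:
        probes = assignment.probes_in(module)
        X = beta.loc[probes, me.index].to_numpy(float)
        e = me[module].to_numpy()
        Xc = X - X.mean(axis=1, keepdims=True)
        ec = e - e.mean()
        denom = np.sqrt((Xc**2).sum(axis=1) * float(ec @ ec))
        denom[denom == 0] = np.inf
        mm = (Xc @ ec) / denom
        rows.append(pd.DataFrame({"probe": probes, "module": module, "MM": mm}))
    if not rows:
        return pd.DataFrame(columns=["probe", "module", "MM"])
    return pd.concat(rows, ignore_index=True)


def probe_significance(beta: pd.DataFrame, trait: pd.Series) -> pd.Series:
    """Per-probe Spearman p-value against a binary trait.

    Constant probes get p = 1 with a warning. Uses the same Spearman
    estimator as the module-level tests.
    """
    shared = beta.columns.intersection(trait.dropna().index)
    t = trait[shared].to_numpy(float)
    out = {}
    n_constant = 0
    for probe in beta.index:
        x = beta.loc[probe, shared].to_numpy(float)
        if np.std(x) == 0:
            out[probe] = 1.0
            n_constant += 1
            continue
        _, p = spearman_test(x, t)
        out[probe] = p
    if n_constant:
        warnings.warn(f"{n_constant} constant probes assigned p = 1")
    return pd.Series(out, name="PS_p")


def mm_ps_relation(membership: pd.DataFrame, ps: pd.Series) -> tuple[float, float]:
    """Pearson correlation of module membership with -log10 probe significance."""
    df = membership.set_index("probe").join(ps.rename("PS_p"), how="inner").dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 probes with both MM and PS")
    neglog = -np.log10(df["PS_p"].to_numpy(float))
    if np.std(neglog) == 0 or df["MM"].std() == 0:
        raise ValueError("degenerate input: MM or PS constant")
    return pearson_test(df["MM"].to_numpy(float), neglog)


def eigengene_group_test(
    me: pd.Series,
    groups: pd.Series,
    regress_out: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests across a 3-level grouping with BH.

    If ``regress_out`` is given (numeric covariates indexed by sample), the
    eigengene is first residualised on them (OLS; residual + intercept).
    Empty or single-sample groups skip their pairs; BH runs over the
    remaining p-values.
    """
    shared = me.index.intersection(groups.dropna().index)
    y = me[shared]
    g = groups[shared]
    if regress_out is not None:
        cov = regress_out.loc[shared]
        frame = pd.DataFrame({"y": y}).T
        meta = cov.reset_index().rename(columns={cov.index.name or "index": "sample"})
        resid = residualize_covariates(frame, meta, list(cov.columns))
        y = resid.loc["y"]
    levels = list(pd.unique(g))
    pairs, pvals = [], []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a = y[g == levels[i]].to_numpy(float)
            b = y[g == levels[j]].to_numpy(float)
            if len(a) < 2 or len(b) < 2:
                warnings.warn(
                    f"pair {levels[i]}/{levels[j]} skipped (group too small)"
                )
                continue
            pairs.append((levels[i], levels[j]))
            pvals.append(rank_sum_test(a, b))
    q = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "group_a": [p[0] for p in pairs],
            "group_b": [p[1] for p in pairs],
            "p": pvals,
            "q": q,
        }
    )
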