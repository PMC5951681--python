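"""Variable selection, permutation importance, and site-level cross-validation
for the GDM.

The selection procedure has three sequential stages:

1. deviance screen — drop any candidate whose single-variable GDM
   (candidate + geography) explains less than 5% of the deviance;
2. correlation screen — among survivors, while any pair of raw site-value
   vectors has |Pearson r| above 0.60, drop the member of the most
   correlated pair with the lower single-variable deviance;
3. permutation importance on the joint model — variables with p > 0.05 or
   importance below a floor are flagged for analyst review (removal is
   opt-in, not automatic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import PairwiseMatrix
from .gdm import GDMModel, fit_gdm, make_pair_table
from .sites import SiteTable


@dataclass
class VariableSelectionReport:
    candidates: list[str]
    single_deviance: dict[str, float]  # stage-1 single-variable deviance explained
    removed_low_deviance: list[str]
    removed_correlated: list[tuple[str, str]]  # (removed, kept-partner)
    importance: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    flagged: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    final_model: GDMModel | None = None

    def to_frame(self) -> pd.DataFrame:
        removed_corr = {v: kept for v, kept in self.removed_correlated}
        rows = []
        for v in self.candidates:
            if v in self.removed_low_deviance:
                stage = "low-deviance"
            elif v in removed_corr:
                stage = f"correlated(with {removed_corr[v]})"
            elif v in self.retained:
                stage = "retained"
            else:
                stage = "removed"
            rows.append(
                {
                    "variable": v,
                    "single_deviance_explained": self.single_deviance.get(v, np.nan),
                    "stage": stage,
                    "importance": self.importance.get(v, np.nan),
                    "p_value": self.p_values.get(v, np.nan),
                    "flagged": v in self.flagged,
                }
            )
        return pd.DataFrame(rows)


def _single_variable_deviance(sites, var, response, geo, n_basis) -> float:
    pt = make_pair_table(sites, [var], response, geo, n_basis=n_basis)
    return fit_gdm(pt).deviance_explained


def permutation_importance(
    sites: SiteTable,
    predictors: list[str],
    response: PairwiseMatrix,
    geo: PairwiseMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    n_basis: int = 3,
) -> tuple[dict[str, float], dict[str, float], GDMModel]:
    """Permutation importance of each predictor in the joint model.

    For each variable, its site values are permuted across sites n_perm
    times, the pair table rebuilt and the model refit; importance is the
    mean percent drop in deviance explained relative to the full model,
    and p is the +1-corrected proportion of permuted fits that explain at
    least as much deviance as the full model.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    full_pt = make_pair_table(sites, predictors, response, geo, n_basis=n_basis)
    full = fit_gdm(full_pt)
    de_full = full.deviance_explained
    rng = np.random.default_rng(seed)
    importance: dict[str, float] = {}
    p_values: dict[str, float] = {}
    for var in predictors:
        drops = np.empty(n_perm)
        n_ge = 0
        for b in range(n_perm):
            df = sites.df.copy()
            df[var] = rng.permutation(df[var].to_numpy())
            perm_sites = SiteTable(df, list(sites.env_columns))
            pt = make_pair_table(perm_sites, predictors, response, geo, n_basis=n_basis)
            de = fit_gdm(pt).deviance_explained
            drops[b] = 100.0 * (de_full - de) / de_full if de_full > 0 else 0.0
            if de >= de_full:
                n_ge += 1
        importance[var] = float(drops.mean())
        p_values[var] = (1 + n_ge) / (n_perm + 1)
    return importance, p_values, full


def select_variables(
    sites: SiteTable,
    candidates: list[str],
    response: PairwiseMatrix,
    geo: PairwiseMatrix,
    deviance_floor: float = 0.05,
    corr_ceiling: float = 0.60,
    n_perm: int = 1000,
    seed: int = 0,
    n_basis: int = 3,
    importance_floor: float = 1.0,
    auto_remove_flagged: bool = False,
) -> VariableSelectionReport:
    if not candidates:
        raise ValueError("need at least one candidate")
    single = {
        v: _single_variable_deviance(sites, v, response, geo, n_basis) for v in candidates
    }
    survivors = [v for v in candidates if single[v] >= deviance_floor]
    removed_low = [v for v in candidates if v not in survivors]

    removed_corr: list[tuple[str, str]] = []
    env = sites.env_values(candidates)
    while len(survivors) > 1:
        sub = env[survivors]
        corr = sub.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= corr_ceiling:
            break
        a, b = survivors[i], survivors[j]
        drop, keep = (a, b) if single[a] <= single[b] else (b, a)
        removed_corr.append((drop, keep))
        survivors.remove(drop)

    report = VariableSelectionReport(
        candidates=list(candidates),
        single_deviance=single,
        removed_low_deviance=removed_low,
        removed_correlated=removed_corr,
        retained=list(survivors),
    )
    if not survivors:
        return report

    importance, p_values, full = permutation_importance(
        sites, survivors, response, geo, n_perm=n_perm, seed=seed, n_basis=n_basis
    )
    report.importance = importance
    report.p_values = p_values
    report.flagged = [
        v for v in survivors if p_values[v] > 0.05 or importance[v] < importance_floor
    ]
    if auto_remove_flagged and report.flagged:
        report.retained = [v for v in survivors if v not in report.flagged]
        if report.retained:
            pt = make_pair_table(sites, report.retained, response, geo, n_basis=n_basis)
            report.final_model = fit_gdm(pt)
        return report
    report.final_model = full
    return report


@dataclass
class CrossValidationResult:
    mean_r: float
    sd_r: float
    per_iteration_r: np.ndarray  # degenerate iterations excluded
    n_degenerate: int
    n_iter: int


def cross_validate(
    sites: SiteTable,
    predictors: list[str],
    response: PairwiseMatrix,
    geo: PairwiseMatrix,
    train_frac: float = 0.70,
    n_iter: int = 1000,
    seed: int = 0,
    n_basis: int = 3,
) -> CrossValidationResult:
    """Site-level holdout validation of GDM predictions.

    Each iteration fits on the pairs among a random ceil(train_frac * S)
    sites and predicts the dissimilarities among the held-out sites only;
    the score is the Pearson correlation of predicted vs observed test-pair
    dissimilarities.  Iterations whose observed or predicted test response
    is constant are excluded from the mean and counted.
    """
    ids = sites.site_ids
    s = len(ids)
    n_train = int(np.ceil(train_frac * s))
    if s - n_train < 2:
        raise ValueError("test set needs at least 2 sites")
    env = sites.env_values(predictors)
    rng = np.random.default_rng(seed)
    rs, n_deg = [], 0
    for _ in range(n_iter):
        perm = rng.permutation(s)
        train, test = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        tr_sites = SiteTable(sites.df.iloc[train].copy(), list(sites.env_columns))
        tr_resp = PairwiseMatrix(
            [ids[i] for i in train], response.values[np.ix_(train, train)], "scaled_fst"
        )
        tr_geo = PairwiseMatrix(
            [ids[i] for i in train], geo.values[np.ix_(train, train)], "geographic"
        )
        model = fit_gdm(make_pair_table(tr_sites, predictors, tr_resp, tr_geo, n_basis))

        ti, tj = np.triu_indices(len(test), k=1)
        obs = response.values[np.ix_(test, test)][ti, tj]
        pred = np.array(
            [
                model.predict(
                    {p: env.iloc[test[i]][p] for p in predictors},
                    {p: env.iloc[test[j]][p] for p in predictors},
                    geo.values[test[i], test[j]],
                )
                for i, j in zip(ti, tj)
            ]
        )
        if np.ptp(obs) == 0 or np.ptp(pred) == 0:
            n_deg += 1
            continue
        rs.append(float(np.corrcoef(obs, pred)[0, 1]))
    rs = np.asarray(rs)
    return CrossValidationResult(
        mean_r=float(rs.mean()) if rs.size else np.nan,
        sd_r=float(rs.std(ddof=1)) if rs.size > 1 else np.nan,
        per_iteration_r=rs,
        n_degenerate=n_deg,
        n_iter=n_iter,
    )
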