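"""Model-object interface over the scoring and inference pipeline.

`CueIntegrationModel` wraps a trial-level response table; `fit()` runs the
full analysis - per-subject d' scoring, the at-or-below-chance exclusion
rule, integration and cue-difference scores, the four planned paired
comparisons per group, fusion-pattern classification, and (with two groups)
the 2x2 mixed ANOVA on integration scores - and returns a
`CueIntegrationResults` carrying every estimate with a text `summary()`.

Example
-------
>>> from cuefusion import CohortSpec, simulate_study, CueIntegrationModel
>>> _, trials, _ = simulate_study(CohortSpec(seed=7))
>>> res = CueIntegrationModel.from_dataframe(trials).fit()
>>> print(res.summary())                            # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import sdt, stats as _stats
from .exceptions import DataError, InvalidSpecificationError

__all__ = ["CueIntegrationModel", "CueIntegrationResults"]


class CueIntegrationModel:
    """Cue-integration analysis of a same-different slant trial table.

    Parameters
    ----------
    trials : DataFrame with columns subject_id, group, condition, trial,
        truth, response (conditions T+, T-, D+, D-, T+D+, T+D-).
    correction : extreme-proportion handling for d' ("loglinear" or "none").
    alpha : per-test significance level of the planned comparisons.
    """

    def __init__(self, trials: pd.DataFrame, *, correction: str = "loglinear",
                 alpha: float = 0.05):
        self.trials = sdt.trials_to_dataframe(trials)
        self.correction = correction
        if not 0 < alpha < 1:
            raise InvalidSpecificationError("alpha must be in (0, 1)")
        self.alpha = alpha

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "CueIntegrationModel":
        return cls(df, **kw)

    @classmethod
    def from_csv(cls, path, **kw) -> "CueIntegrationModel":
        try:
            df = pd.read_csv(path, dtype={"subject_id": str, "group": str})
        except (ValueError, OSError) as e:
            raise DataError(f"cannot read trial table {path}: {e}") from e
        return cls(df, **kw)

    def fit(self) -> "CueIntegrationResults":
        scores = sdt.score_table(self.trials, self.correction)
        retained, excluded = sdt.apply_exclusions(scores)
        by_group: dict[str, list] = {}
        for s in retained:
            by_group.setdefault(s.group, []).append(s)

        integration = {s.subject_id: sdt.integration_scores(s) for s in retained}
        cue_diffs = {s.subject_id: sdt.cue_difference_scores(s) for s in retained}

        comparisons, classification = {}, {}
        for g, gs in sorted(by_group.items()):
            if len(gs) >= 2:
                comparisons[g] = sdt.planned_comparisons(gs, self.alpha)
                classification[g] = sdt.classify_fusion_pattern(gs, self.alpha)

        anova = None
        if len(by_group) == 2:
            subs = [s for g in sorted(by_group) for s in by_group[g]]
            anova = _stats.mixed_anova_2x2(
                [integration[s.subject_id].congruent_score for s in subs],
                [integration[s.subject_id].incongruent_score for s in subs],
                [s.group for s in subs])

        return CueIntegrationResults(
            model=self, condition_scores=retained, excluded=excluded,
            integration=integration, cue_differences=cue_diffs,
            comparisons=comparisons, classification=classification,
            anova=anova)


@dataclass
class CueIntegrationResults:
    """Fitted estimates, tests and classification for one trial table."""

    model: CueIntegrationModel
    condition_scores: list
    excluded: list
    integration: dict
    cue_differences: dict
    comparisons: dict
    classification: dict
    anova: dict | None

    # ---- tabular views ---------------------------------------------------

    def scores_frame(self) -> pd.DataFrame:
        """Per-subject d' by condition plus integration scores."""
        rows = []
        for s in self.condition_scores:
            row = {"subject_id": s.subject_id, "group": s.group}
            row.update({f"dprime_{c}": s.dprime.get(c, np.nan)
                        for c in ("T+", "T-", "D+", "D-", "T+D+", "T+D-")})
            ints = self.integration[s.subject_id]
            row["congruent_score"] = ints.congruent_score
            row["incongruent_score"] = ints.incongruent_score
            rows.append(row)
        return pd.DataFrame(rows)

    def group_means(self) -> pd.DataFrame:
        """Group mean d' and SE per analysed condition (Fig.-2-style table)."""
        df = self.scores_frame()
        out = []
        for g, sub in df.groupby("group"):
            for c in ("T+", "D+", "D-", "T+D+", "T+D-"):
                col = sub[f"dprime_{c}"].dropna()
                out.append({"group": g, "condition": c, "mean_dprime": col.mean(),
                            "se": col.std(ddof=1) / np.sqrt(len(col)),
                            "n": len(col)})
        return pd.DataFrame(out)

    # ---- reporting -------------------------------------------------------

    def summary(self) -> str:
        lines = ["Cue-integration analysis (same-different slant task)",
                 "=" * 56]
        n_total = len(self.condition_scores) + len(self.excluded)
        lines.append(f"subjects analysed: {len(self.condition_scores)} "
                     f"(of {n_total}; {len(self.excluded)} excluded at d' <= 0 "
                     "on a single-cue condition)")
        for s, reason in self.excluded:
            lines.append(f"  excluded {s.subject_id}: {reason}")
        gm = self.group_means()
        lines.append("\nGroup mean d' (SE):")
        for g, sub in gm.groupby("group"):
            cells = ", ".join(f"{r.condition} {r.mean_dprime:.2f} ({r.se:.2f})"
                              for r in sub.itertuples())
            lines.append(f"  {g}: {cells}")
        lines.append("\nPlanned comparisons (paired t, Cohen's d = |t|/sqrt(n)):")
        for g, comps in self.comparisons.items():
            for name, (res, hit) in comps.items():
                star = " *" if hit else ""
                lines.append(f"  {g} {name}: t({res.df}) = {res.t:.2f}, "
                             f"p = {res.p:.3f}, d = {res.cohens_d:.2f}{star}")
            lines.append(f"  {g} fusion pattern: {self.classification[g]}")
        if self.anova is not None:
            lines.append("\n2x2 mixed ANOVA on integration scores "
                         "(condition x group):")
            for eff, r in self.anova.items():
                lines.append(f"  {eff}: F({r.df1},{r.df2}) = {r.F:.2f}, "
                             f"p = {r.p:.3f}, partial eta^2 = {r.partial_eta_sq:.3f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        doc = {
            "n_analysed": len(self.condition_scores),
            "excluded": [{"subject_id": s.subject_id, "reason": r}
                         for s, r in self.excluded],
            "group_means": self.group_means().to_dict(orient="records"),
            "tests": [
                {"group": g, "name": name, "statistic": res.t, "df": res.df,
                 "p": res.p, "effect_size": res.cohens_d, "significant": hit}
                for g, comps in self.comparisons.items()
                for name, (res, hit) in comps.items()],
            "classification": self.classification,
            "anova": {eff: asdict(r) for eff, r in self.anova.items()}
            if self.anova is not None else None,
        }
        return json.dumps(doc, indent=2)

    # ---- plotting --------------------------------------------------------

    def plot_condition_means(self, ax=None):
        """Bar chart of group mean d' with SE whiskers, one panel per group."""
        import matplotlib.pyplot as plt

        gm = self.group_means()
        groups = sorted(gm["group"].unique())
        if ax is None:
            _, axes = plt.subplots(1, len(groups), figsize=(4 * len(groups), 3),
                                   sharey=True, squeeze=False)
            axes = axes[0]
        else:
            axes = np.atleast_1d(ax)
        order = ["T+", "D+", "D-", "T+D+", "T+D-"]
        for a, g in zip(axes, groups):
            sub = gm[gm["group"] == g].set_index("condition").loc[order]
            a.bar(order, sub["mean_dprime"], yerr=sub["se"], capsize=3,
                  color="0.6", edgecolor="black")
            a.set_title(g)
            a.set_ylabel("d'")
            a.axhline(0, color="black", lw=0.8)
        return axes
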