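"""Markdown rendering of analysis results.

Sections mirror the standard cost-of-illness reporting layout: the annual
cost table with component means/SDs and shares, the lifetime Markov summary
with per-state attribution, and the two-part coefficient tables.  Stages
that were not run are marked absent, never treated as failures.
"""

from __future__ import annotations

from .costing import (
    DIRECT_FIELDS,
    INDIRECT_FIELDS,
    AnnualCostBreakdown,
    convert_to_ppp,
)
from .markov import COSTED_LABELS, MarkovResult
from .twopart import TwoPartFit

_LABELS = {
    "direct_medicine": "Medicine",
    "direct_treatment": "Treatment",
    "direct_diagnostic": "Diagnostic",
    "direct_non_medical": "Non-medical",
    "indirect_premature_death": "Premature death",
    "indirect_absenteeism": "Absenteeism",
    "indirect_presenteeism": "Presenteeism",
    "indirect_job_change": "Job change",
    "indirect_unpaid_work": "Unpaid work",
}


def _money(x: float) -> str:
    return f"{x:,.1f}"


def render_breakdown(b: AnnualCostBreakdown, toman_per_ppp: float | None = None) -> str:
    lines = ["## Annual cost per patient", ""]
    ppp_col = " | PPP$" if toman_per_ppp else ""
    lines.append(f"| Component | Mean (Toman/yr) | SD{ppp_col} |")
    lines.append("|---|---:|---:" + ("|---:" if toman_per_ppp else "") + "|")

    def row(label: str, mean: float, sd: float | None) -> str:
        cells = [label, _money(mean), _money(sd) if sd is not None else ""]
        if toman_per_ppp:
            cells.append(f"{convert_to_ppp(mean, toman_per_ppp):,.2f}")
        return "| " + " | ".join(cells) + " |"

    for f in DIRECT_FIELDS:
        lines.append(row(_LABELS[f], b.component_means[f], b.component_sds[f]))
    lines.append(row("**Direct total**", b.direct_total, None))
    for f in INDIRECT_FIELDS:
        lines.append(row(_LABELS[f], b.component_means[f], b.component_sds[f]))
    lines.append(row("**Indirect total**", b.indirect_total, None))
    lines.append(row("**Grand total**", b.grand_total, b.grand_total_sd))
    lines.append("")
    lines.append(f"Direct share: {b.share_direct}% (raw {b.share_direct_raw:.2f}%), "
                 f"indirect share: {b.share_indirect}% (raw {b.share_indirect_raw:.2f}%).")
    dm = b.direct_medical_shares
    lines.append(
        "Direct-medical composition: medicine "
        f"{dm['direct_medicine']}%, treatment {dm['direct_treatment']}%, "
        f"diagnostic {dm['direct_diagnostic']}%.")
    cls = ", ".join(f"class {k}: {_money(v)} ({b.class_shares.get(k, '–')}%)"
                    for k, v in b.class_means.items())
    lines.append(f"Per-class annual means: {cls}.")
    if b.degenerate_sd:
        lines.append("*Single-observation cohort: SDs degenerate (reported as 0).*")
    lines.append("")
    return "\n".join(lines)


def render_markov(r: MarkovResult) -> str:
    lines = ["## Lifetime cost (six-state Markov model)", ""]
    lines.append(f"Expected lifetime cost per patient: **{_money(r.lifetime_cost)} Toman** "
                 f"(discount rate {r.discount_rate:.1%}, "
                 f"{r.occupancy.shape[0] - 1} one-year cycles).")
    lines.append(f"Expected life years: {r.life_years:.2f}; "
                 f"probability of heart-failure death by horizon: {r.hf_death_probability:.3f}.")
    lines.append("")
    lines.append("| State | Lifetime cost (Toman) | Share |")
    lines.append("|---|---:|---:|")
    for i, label in enumerate(COSTED_LABELS):
        share = f"{int(r.shares_rounded[i])}%" if r.shares_rounded is not None else "–"
        lines.append(f"| {label} | {_money(r.state_costs[i])} | {share} |")
    lines.append("")
    return "\n".join(lines)


def render_two_part(fit: TwoPartFit) -> str:
    lines = ["## Two-part cost regression", ""]
    for name, part in (("A. Any cost (Probit)", fit.probit),
                       (f"B. Positive cost (GLM, {fit.glm.family}/{fit.glm.link})",
                        fit.glm)):
        lines.append(f"### {name}")
        lines.append("")
        lines.append("| Covariate | Coef | Std.Err | Z | P>|z| | 95% CI |")
        lines.append("|---|---:|---:|---:|---:|---:|")
        for cov, row in part.table.iterrows():
            lines.append(
                f"| {cov} | {row['coef']:.7g} | {row['std_err']:.7g} | "
                f"{row['z']:.2f} | {row['p_value']:.3f} | "
                f"[{row['ci_low']:.7g}, {row['ci_high']:.7g}] |")
        lines.append("")
        lines.append(f"Log-likelihood: {part.loglik:.4f} (n = {part.n})")
        lines.append("")
    crit = fit.criteria()
    lines.append(f"Overall log-likelihood {fit.loglik:.4f}; "
                 f"AIC {crit['aic']:.3f} (whole-model), "
                 f"{crit['aic_per_obs']:.5f} (per observation); "
                 f"BIC {crit['bic']:.3f} (Schwarz)"
                 + (f", {crit['bic_deviance']:.3f} (deviance-based)"
                    if "bic_deviance" in crit else "") + ".")
    lines.append("")
    return "\n".join(lines)


def render_report(breakdown: AnnualCostBreakdown | None = None,
                  markov_result: MarkovResult | None = None,
                  fit: TwoPartFit | None = None,
                  toman_per_ppp: float | None = None) -> str:
    """Assemble the full markdown report; absent stages are noted."""
    parts = ["# Heart-failure cost-of-illness report", ""]
    if breakdown is not None:
        parts.append(render_breakdown(breakdown, toman_per_ppp))
    else:
        parts.append("## Annual cost per patient\n\n*Not computed in this run.*\n")
    if markov_result is not None:
        parts.append(render_markov(markov_result))
    else:
        parts.append("## Lifetime cost (six-state Markov model)\n\n*Not computed in this run.*\n")
    if fit is not None:
        parts.append(render_two_part(fit))
    else:
        parts.append("## Two-part cost regression\n\n*Not computed in this run.*\n")
    return "\n".join(parts)
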