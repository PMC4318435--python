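"""Expression-based gene classification.

Genes are classified from log2 expression matrices over two genotypes
(wild type, mutant) x two treatments (control, treated) x replicates:

- treatment response: induced (SI, log2 FC >= 2 and p <= 0.05) or repressed
  (SR, log2 FC <= -2 and p <= 0.05) using the wild-type contrast;
- baseline: silent (SIL, every wild-type value <= 0) or constitutive
  (CON, every wild-type value >= 3), only for genes that are not SI/SR;
- genotype dependence: a per-gene two-way fixed-effects ANOVA; treatment
  regulation is gated on the treatment main effect q-value and dependence on
  the genotype x treatment interaction p (a flag selects the genotype main
  effect instead).  Dependence p <= 1e-4 -> dependent (ND); p >= 0.1 ->
  independent (NI); the gap in between stays unclassified.

The differential-expression p for SI/SR is a plain two-sample Student t
between wild-type control and treated replicates (moderated statistics are
out of scope).  Zero-variance inputs follow a fixed convention: equal means
-> p = 1; unequal means with zero variance -> p = the smallest positive
float, flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

TINY_P = float(np.finfo(float).tiny)

GENOTYPES = ("Col0", "npr1")
TREATMENTS = ("control", "SA")

EXPRESSION_COLUMNS = ("gene_id", "genotype", "treatment", "replicate", "value")


# ---------------------------------------------------------------------------
# two-sample t with the zero-variance convention
# ---------------------------------------------------------------------------


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Equal-variance two-sample t-test returning ``(t, p)``.

    Degenerate (zero pooled variance) cases: equal means -> (0, 1);
    unequal means -> (+/-inf, tiny p), with a log warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("two_sample_t requires >= 2 observations per group")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        logger.warning("two_sample_t: zero variance with unequal means; p set to tiny")
        return float(np.sign(a.mean() - b.mean()) * np.inf), TINY_P
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaResult:
    """Fixed-effects 2x2 ANOVA decomposition for one gene."""

    f_genotype: float
    p_genotype: float
    f_treatment: float
    p_treatment: float
    f_interaction: float
    p_interaction: float
    df_error: int
    ss_genotype: float
    ss_treatment: float
    ss_interaction: float
    ss_error: float
    degenerate: bool = False


def anova_two_way(values: np.ndarray) -> AnovaResult:
    """Classical two-way fixed-effects ANOVA on a balanced 2x2xr design.

    ``values`` has shape ``(2, 2, r)`` indexed (genotype, treatment,
    replicate) with r >= 2.  F = MS_effect / MS_error with df (1, 4(r-1)).
    A zero error variance is flagged degenerate; effects with zero sum of
    squares then get p = 1 and non-zero effects p = tiny.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3 or values.shape[:2] != (2, 2):
        raise ValidationError("anova_two_way expects a (2, 2, r) array")
    r = values.shape[2]
    if r < 2:
        raise ValidationError("anova_two_way requires r >= 2 replicates per cell")

    grand = values.mean()
    m_geno = values.mean(axis=(1, 2))      # per genotype
    m_treat = values.mean(axis=(0, 2))     # per treatment
    m_cell = values.mean(axis=2)           # per cell

    ss_geno = 2 * r * float(((m_geno - grand) ** 2).sum())
    ss_treat = 2 * r * float(((m_treat - grand) ** 2).sum())
    ss_cells = r * float(((m_cell - grand) ** 2).sum())
    ss_int = ss_cells - ss_geno - ss_treat
    ss_int = max(ss_int, 0.0)  # guard rounding
    ss_err = float(((values - m_cell[:, :, None]) ** 2).sum())
    df_err = 4 * (r - 1)

    scale = float((values ** 2).sum()) or 1.0
    degenerate = ss_err <= 1e-12 * scale

    def f_and_p(ss_effect: float) -> tuple[float, float]:
        if degenerate:
            if ss_effect <= 1e-12 * scale:
                return 0.0, 1.0
            return float("inf"), TINY_P
        f = ss_effect / (ss_err / df_err)
        return float(f), float(stats.f.sf(f, 1, df_err))

    fg, pg = f_and_p(ss_geno)
    ft, pt = f_and_p(ss_treat)
    fi, pi = f_and_p(ss_int)
    if degenerate:
        logger.warning("anova_two_way: zero error variance; degenerate result flagged")
    return AnovaResult(
        f_genotype=fg,
        p_genotype=pg,
        f_treatment=ft,
        p_treatment=pt,
        f_interaction=fi,
        p_interaction=pi,
        df_error=df_err,
        ss_genotype=ss_geno,
        ss_treatment=ss_treat,
        ss_interaction=ss_int,
        ss_error=ss_err,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# p-value adjustment
# ---------------------------------------------------------------------------


def adjust_pvalues(pvalues: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg (default) or Storey.

    The Storey variant uses a fixed lambda = 0.5 for the pi0 estimate and
    otherwise follows the BH step-up construction scaled by pi0.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if method == "bh":
        from statsmodels.stats.multitest import multipletests

        return multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        lam = 0.5
        m = p.size
        pi0 = min(1.0, (np.sum(p > lam) / (m * (1.0 - lam))) or 1.0 / m)
        order = np.argsort(p, kind="mergesort")
        ranked = p[order]
        q = pi0 * ranked * m / np.arange(1, m + 1)
        q = np.minimum.accumulate(q[::-1])[::-1]
        q = np.clip(q, 0.0, 1.0)
        out = np.empty(m)
        out[order] = q
        return out
    raise ValidationError(f"unknown adjustment method: {method!r}")


# ---------------------------------------------------------------------------
# classification rules
# ---------------------------------------------------------------------------


def classify_sa_response(
    log2_fc: float,
    p_de: float,
    fc_up: float = 2.0,
    fc_down: float = -2.0,
    p_max: float = 0.05,
) -> str | None:
    """'SI' / 'SR' / None from the wild-type treatment contrast (inclusive bounds)."""
    if p_de is None or (isinstance(p_de, float) and np.isnan(p_de)):
        raise ValidationError("classify_sa_response: missing differential-expression p")
    if p_de > p_max:
        return None
    if log2_fc >= fc_up:
        return "SI"
    if log2_fc <= fc_down:
        return "SR"
    return None


def classify_baseline(
    wildtype_values: Sequence[float],
    sil_max: float = 0.0,
    con_min: float = 3.0,
) -> str | None:
    """'SIL' / 'CON' / None from all wild-type replicate values (both treatments).

    Consistency is required across every replicate of both conditions; the
    caller must additionally ensure the gene is not SI/SR.
    """
    v = np.asarray(wildtype_values, dtype=float)
    if v.size == 0:
        raise ValidationError("classify_baseline: no values")
    if np.all(v <= sil_max):
        return "SIL"
    if np.all(v >= con_min):
        return "CON"
    return None


def classify_npr1_dependence(
    anova: AnovaResult,
    q_treatment: float,
    log2_fc: float,
    q_reg_max: float = 0.05,
    p_nd_max: float = 1e-4,
    p_ni_min: float = 0.1,
    fc_up: float = 2.0,
    fc_down: float = -2.0,
    dependence_term: Literal["interaction", "genotype"] = "interaction",
) -> str:
    """Subclass a gene as SI-ND / SR-ND / SI-NI / SR-NI or 'unclassified'.

    Regulated iff the treatment-effect q <= ``q_reg_max``; dependence from
    the chosen ANOVA term p: <= ``p_nd_max`` -> ND, >= ``p_ni_min`` -> NI,
    in between -> unclassified.  The SI/SR split follows the sign of the
    wild-type log2 fold change at the +/-2 thresholds.
    """
    if q_treatment > q_reg_max:
        return "unclassified"
    p_dep = (
        anova.p_interaction if dependence_term == "interaction" else anova.p_genotype
    )
    if p_dep <= p_nd_max:
        dep = "ND"
    elif p_dep >= p_ni_min:
        dep = "NI"
    else:
        return "unclassified"
    if log2_fc is None or (isinstance(log2_fc, float) and np.isnan(log2_fc)):
        raise ValidationError("classify_npr1_dependence: missing fold change")
    if log2_fc >= fc_up:
        return f"SI-{dep}"
    if log2_fc <= fc_down:
        return f"SR-{dep}"
    return "unclassified"


# ---------------------------------------------------------------------------
# table-level driver
# ---------------------------------------------------------------------------


def _gene_cube(gdf: pd.DataFrame) -> np.ndarray:
    reps = sorted(gdf["replicate"].unique())
    cube = np.empty((2, 2, len(reps)))
    for gi, geno in enumerate(GENOTYPES):
        for ti, treat in enumerate(TREATMENTS):
            cell = gdf[(gdf["genotype"] == geno) & (gdf["treatment"] == treat)]
            cell = cell.sort_values("replicate")
            if len(cell) != len(reps):
                raise ValidationError(
                    f"unbalanced design for gene {gdf['gene_id'].iloc[0]}: "
                    f"cell {geno}/{treat} has {len(cell)} replicates"
                )
            cube[gi, ti, :] = cell["value"].to_numpy()
    return cube


def classify_genes(
    expression: pd.DataFrame,
    dependence_term: Literal["interaction", "genotype"] = "interaction",
    adjust_method: str = "bh",
    **thresholds,
) -> pd.DataFrame:
    """Classify every gene in a long-format expression table.

    ``expression`` columns: gene_id, genotype (Col0/npr1), treatment
    (control/SA), replicate, value.  Returns one row per gene with the
    fold change, test statistics, the SA-response class (SI/SR), the
    baseline class (SIL/CON) and the dependence subclass.
    """
    missing = set(EXPRESSION_COLUMNS) - set(expression.columns)
    if missing:
        raise ValidationError(f"expression table missing columns: {sorted(missing)}")

    records = []
    anovas: dict[str, AnovaResult] = {}
    for gene_id, gdf in expression.groupby("gene_id", sort=True):
        cube = _gene_cube(gdf)
        wt_control = cube[0, 0, :]
        wt_sa = cube[0, 1, :]
        log2_fc = float(wt_sa.mean() - wt_control.mean())
        _, p_de = two_sample_t(wt_sa, wt_control)
        anovas[gene_id] = anova_two_way(cube)
        records.append(
            {
                "gene_id": gene_id,
                "log2_fc": log2_fc,
                "p_de": p_de,
                "p_treatment": anovas[gene_id].p_treatment,
                "p_interaction": anovas[gene_id].p_interaction,
                "p_genotype": anovas[gene_id].p_genotype,
                "wt_values": np.concatenate([wt_control, wt_sa]),
            }
        )
    df = pd.DataFrame(records)
    df["q_treatment"] = adjust_pvalues(df["p_treatment"].to_numpy(), adjust_method)

    sa_kw = {k: thresholds[k] for k in ("fc_up", "fc_down", "p_max") if k in thresholds}
    base_kw = {k: thresholds[k] for k in ("sil_max", "con_min") if k in thresholds}
    dep_kw = {
        k: thresholds[k]
        for k in ("q_reg_max", "p_nd_max", "p_ni_min", "fc_up", "fc_down")
        if k in thresholds
    }

    sa_class, baseline, subclass = [], [], []
    for row in df.itertuples(index=False):
        sa = classify_sa_response(row.log2_fc, row.p_de, **sa_kw)
        sa_class.append(sa)
        baseline.append(
            None if sa is not None else classify_baseline(row.wt_values, **base_kw)
        )
        subclass.append(
            classify_npr1_dependence(
                anovas[row.gene_id],
                row.q_treatment,
                row.log2_fc,
                dependence_term=dependence_term,
                **dep_kw,
            )
        )
    df["sa_class"] = sa_class
    df["baseline_class"] = baseline
    df["subclass"] = subclass
    df["class"] = [
        s if s is not None else (b if b is not None else "none")
        for s, b in zip(sa_class, baseline)
    ]
    return df.drop(columns=["wt_values"])


def read_expression_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EXPRESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_groups_table(classified: pd.DataFrame, path) -> None:
    out = classified[["gene_id", "class", "subclass"]].copy()
    out.to_csv(path, sep="\t", index=False)
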