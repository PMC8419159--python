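"""Relative expression by the comparative-Ct (2^-ddCt) method.

Raw qPCR Ct values are normalized within each sample against a reference
gene (dCt = Ct_target - Ct_reference, paired within the same replicate), the
normalized values are contrasted between treated and control groups
(ddCt = mean dCt_treated - mean dCt_control) and exponentiated to a relative
quantity RQ = 2^-ddCt. An RQ below 1 is additionally rendered as a
"decrease fold" 1/RQ, the convention used when reporting down-regulation.

Group comparison runs on the dCt scale (log2 expression, approximately
normal) with an equal-variance two-sided Student's t test (Welch available
behind a flag); dispersion is summarized as the SEM of per-sample RQs, the
display convention for bar charts of relative expression. Genes with no
amplification rows at all are flagged undetectable and produce no numbers —
no imputation is attempted. No multiple-testing correction is applied across
genes by default.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .graph_io import DEFAULT_REFERENCE_GENE, validate_ct_table

DEFAULT_ALPHA = 0.05

RESULT_COLUMNS = [
    "gene",
    "timepoint",
    "detectable",
    "mean_dct_control",
    "mean_dct_treated",
    "ddct",
    "rq",
    "direction",
    "decrease_fold",
    "increase_fold",
    "sem_rq",
    "n_control",
    "n_treated",
    "p_value",
    "significant",
]


def delta_ct(
    records: pd.DataFrame,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    pair_by_replicate: bool = True,
) -> pd.DataFrame:
    """Reference-normalize Ct values: dCt = Ct_target - Ct_reference.

    By default the target pairs with the reference measured in the *same
    sample and replicate*; with ``pair_by_replicate=False`` the sample's mean
    reference Ct is used instead. Returns the input rows for non-reference
    genes with an added ``dct`` column.

    Raises ``ValueError`` naming the first sample that lacks the reference
    gene (or the specific replicate, under replicate pairing).
    """
    df = validate_ct_table(records, reference_gene=None)
    ref = df[df["gene"] == reference_gene]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent from the table")
    targets = df[df["gene"] != reference_gene].copy()
    if pair_by_replicate:
        key = ["sample", "replicate"]
    else:
        key = ["sample"]
    ref_ct = ref.groupby(key)["ct"].mean()
    idx = pd.MultiIndex.from_frame(targets[key]) if len(key) > 1 else targets[key[0]]
    matched = ref_ct.reindex(idx)
    if matched.isna().any():
        missing = targets.loc[np.asarray(matched.isna()), key].iloc[0].tolist()
        raise ValueError(
            f"sample block {missing} has no {reference_gene!r} measurement to pair with"
        )
    targets["dct"] = targets["ct"].to_numpy() - matched.to_numpy()
    return targets


def ddct_fold(dct_treated: Sequence[float], dct_control: Sequence[float]) -> dict:
    """Core comparative-Ct quantities for one gene/timepoint contrast.

    ddCt = mean(dCt treated) - mean(dCt control); RQ = 2^-ddCt; when RQ < 1
    the decrease fold 1/RQ is reported, when RQ > 1 the increase fold RQ.
    """
    t = np.asarray(list(dct_treated), dtype=float)
    c = np.asarray(list(dct_control), dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("both treated and control groups need at least one dCt value")
    ddct = float(t.mean() - c.mean())
    rq = 2.0 ** (-ddct)
    return {
        "mean_dct_control": float(c.mean()),
        "mean_dct_treated": float(t.mean()),
        "ddct": ddct,
        "rq": rq,
        "direction": "decrease" if rq < 1 else ("increase" if rq > 1 else "none"),
        "decrease_fold": 1.0 / rq if rq < 1 else math.nan,
        "increase_fold": rq if rq > 1 else math.nan,
    }


def group_test(
    dct_treated: Sequence[float],
    dct_control: Sequence[float],
    welch: bool = False,
) -> float:
    """Two-sided two-sample t test on dCt values (Student's by default).

    Degenerate case: if both groups have zero variance, p is 1 for equal
    means and 0 otherwise.
    """
    t = np.asarray(list(dct_treated), dtype=float)
    c = np.asarray(list(dct_control), dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("group_test needs >= 2 values per group")
    if np.var(t) == 0.0 and np.var(c) == 0.0:
        return 1.0 if t.mean() == c.mean() else 0.0
    res = stats.ttest_ind(t, c, equal_var=not welch)
    return float(res.pvalue)


def summarize(
    records: pd.DataFrame,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    genes: Iterable[str] | None = None,
    timepoints: Iterable[float] | None = None,
    alpha: float = DEFAULT_ALPHA,
    welch: bool = False,
    pair_by_replicate: bool = True,
) -> pd.DataFrame:
    """Per gene x timepoint fold-change table from a validated Ct table.

    For each gene and timepoint the treated and control dCt values are
    contrasted (:func:`ddct_fold`, :func:`group_test`); the SEM column is the
    standard error of per-sample RQs (each sample's mean dCt against the
    pooled control mean), the convention for error bars across independent
    experiments. Genes listed in ``genes`` but absent from the table appear
    once per timepoint with ``detectable=False`` and no numeric output.
    """
    df = validate_ct_table(records, reference_gene=reference_gene)
    normalized = delta_ct(df, reference_gene, pair_by_replicate=pair_by_replicate)
    tps = sorted(set(normalized["timepoint"]) if timepoints is None else set(timepoints))
    observed = sorted(set(normalized["gene"]))
    wanted = observed if genes is None else [g for g in dict.fromkeys(genes) if g != reference_gene]

    rows = []
    for gene in wanted:
        sub = normalized[normalized["gene"] == gene]
        for tp in tps:
            block = sub[sub["timepoint"] == tp]
            treated = block.loc[block["condition"] == "treated", ["sample", "dct"]]
            control = block.loc[block["condition"] == "control", ["sample", "dct"]]
            if treated.empty or control.empty:
                rows.append({"gene": gene, "timepoint": tp, "detectable": False})
                continue
            core = ddct_fold(treated["dct"], control["dct"])
            control_mean = core["mean_dct_control"]
            per_sample_rq = 2.0 ** -(
                treated.groupby("sample")["dct"].mean() - control_mean
            )
            sem = (
                float(per_sample_rq.std(ddof=1) / np.sqrt(len(per_sample_rq)))
                if len(per_sample_rq) > 1
                else math.nan
            )
            if len(treated) >= 2 and len(control) >= 2:
                p = group_test(treated["dct"], control["dct"], welch=welch)
            else:
                p = math.nan
            rows.append(
                {
                    "gene": gene,
                    "timepoint": tp,
                    "detectable": True,
                    **core,
                    "sem_rq": sem,
                    "n_control": len(control),
                    "n_treated": len(treated),
                    "p_value": p,
                    "significant": bool(p < alpha) if not math.isnan(p) else False,
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
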