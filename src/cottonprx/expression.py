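"""qPCR fold changes (three-step 2^-dCt procedure) and FPKM matrix prep.

Fold changes follow the three steps of the qPCR analysis verbatim:

1. housekeeping normalization per replicate:
   dCt1 = Ct(target) - Ct(reference)
2. comparison against the control series at 0 h:
   dCt2 = dCt1(stress, t) - dCt1(control, 0 h)
3. fold change: FC = 2 ** (-dCt2)

The mean and standard deviation are taken over replicate-level fold
changes (three replicates in the default design), matching error bars
computed on FC rather than on dCt.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CT_COLUMNS = [
    "gene", "condition", "timepoint_h", "replicate", "ct_target", "ct_reference",
]


def _validate_ct(df: pd.DataFrame, label: str) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{label}: missing columns {missing}")
    for col in ("ct_target", "ct_reference"):
        vals = df[col]
        if ((vals <= 0) | (vals >= 45)).any():
            raise ValueError(f"{label}: {col} values must lie in (0, 45)")
    return df


def fold_change(stress: pd.DataFrame, control: pd.DataFrame) -> pd.DataFrame:
    """Per gene/timepoint fold change of a stress series vs. control 0 h.

    Replicates are paired by index between the stress measurement and the
    control 0 h baseline of the same gene.  Returns one row per
    gene/condition/timepoint with mean_fc, sd_fc (ddof=1 over replicates;
    0 for a single replicate) and n.
    """
    stress = _validate_ct(stress, "stress")
    control = _validate_ct(control, "control")

    baseline = control[control["timepoint_h"] == 0]
    if baseline.empty:
        raise ValueError("control series has no 0 h timepoint")
    base_dct1 = (
        baseline.assign(dct1=baseline["ct_target"] - baseline["ct_reference"])
        .set_index(["gene", "replicate"])["dct1"]
    )

    rows = []
    grouped = stress.groupby(["gene", "condition", "timepoint_h"], sort=True)
    for (gene, condition, t), grp in grouped:
        fcs = []
        for _, r in grp.iterrows():
            key = (gene, r["replicate"])
            if key not in base_dct1.index:
                raise ValueError(
                    f"missing control 0 h baseline for gene {gene!r} "
                    f"replicate {r['replicate']!r}"
                )
            dct1 = r["ct_target"] - r["ct_reference"]
            dct2 = dct1 - base_dct1.loc[key]
            fcs.append(2.0 ** (-dct2))
        fcs = np.asarray(fcs, dtype=float)
        sd = float(fcs.std(ddof=1)) if len(fcs) > 1 else 0.0
        rows.append((gene, condition, t, float(fcs.mean()), sd, len(fcs)))
    return pd.DataFrame(
        rows,
        columns=["gene", "condition", "timepoint_h", "mean_fc", "sd_fc", "n"],
    )


def log2_matrix(
    fpkm: pd.DataFrame, pseudocount: float = 1.0, zscore: bool = False
) -> pd.DataFrame:
    """log2(FPKM + pseudocount) of a genes x tissues matrix.

    The pseudocount keeps unexpressed genes (FPKM 0) finite at 0.0.  With
    ``zscore`` each gene row is additionally standardized to mean 0, SD 1
    (rows with zero variance are left at 0).
    """
    if (fpkm.to_numpy() < 0).any():
        raise ValueError("FPKM values must be nonnegative")
    out = np.log2(fpkm + pseudocount)
    if zscore:
        mu = out.mean(axis=1)
        sd = out.std(axis=1, ddof=0)
        out = out.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return out
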