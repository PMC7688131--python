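"""ddCT relative quantification of qRT-PCR threshold-cycle data.

dCt = Ct(target) - Ct(reference); ddCt = dCt(sample) - dCt(calibrator);
RQ = 2^(-ddCt), i.e. the classic ddCT method with amplification efficiency
fixed at 2.  The calibrator may be a named sample or ``"mean"`` (the cohort
mean dCt), in which case the product of RQs over samples equals 1.

RQ values are log2-transformed (``log2_rq = -ddCt``) before entering
regression formulas trained on log2 microarray intensities; this bridge is
this package's convention and is reported alongside the raw RQ.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["QpcrError", "read_ct_table", "relative_expression_ddct"]


class QpcrError(ValueError):
    pass


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct CSV with columns sample, gene, ct[, replicate]."""
    df = pd.read_csv(path)
    missing = {"sample", "gene", "ct"} - set(df.columns)
    if missing:
        raise QpcrError(f"Ct table missing columns: {sorted(missing)}")
    return df


def _mean_ct(table: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates on the Ct scale; samples x genes."""
    ct = table.groupby(["sample", "gene"])["ct"].mean().unstack("gene")
    if ((ct <= 0) | ~np.isfinite(ct)).any().any():
        bad = ct.index[((ct <= 0) | ~np.isfinite(ct)).any(axis=1)]
        raise QpcrError(f"non-positive or non-finite Ct for samples: {list(bad)}")
    return ct


def relative_expression_ddct(
    table: pd.DataFrame,
    target_gene: str,
    reference_gene: str = "GAPDH",
    calibrator: str = "mean",
) -> pd.DataFrame:
    """Per-sample relative quantity of a target gene by ddCT.

    ``table`` is tidy (sample, gene, ct[, replicate]); technical replicates
    are averaged on the Ct scale first.  Returns a DataFrame indexed by
    sample with columns dct, ddct, rq, log2_rq.
    """
    ct = _mean_ct(table)
    for gene in (target_gene, reference_gene):
        if gene not in ct.columns:
            raise QpcrError(f"gene {gene!r} absent from Ct table")
    missing = ct.index[ct[[target_gene, reference_gene]].isna().any(axis=1)]
    if len(missing):
        raise QpcrError(
            f"missing Ct for {target_gene}/{reference_gene} in samples: {list(missing)}"
        )
    dct = ct[target_gene] - ct[reference_gene]
    if calibrator == "mean":
        ref_dct = dct.mean()
    else:
        if calibrator not in dct.index:
            raise QpcrError(f"calibrator sample {calibrator!r} not found")
        ref_dct = dct.loc[calibrator]
    ddct = dct - ref_dct
    out = pd.DataFrame(
        {
            "dct": dct,
            "ddct": ddct,
            "rq": np.power(2.0, -ddct),
            "log2_rq": -ddct,
        }
    )
    out.index.name = "sample"
    return out
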