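"""Technical-variation adjustment via control-probe principal components.

Array control probes measure technical performance (hybridization,
conversion, staining) rather than biology, so their leading principal
components capture plate/chip batch structure.  The first PCs (30 by
default, as in Lehne-style pipelines) are attached to the sample table and
enter every downstream multivariable model as covariates.  Negative control
probes — which measure background, not batch — are excluded.

PCA is performed on the beta values of the control probes, centred probe-
wise; PC signs are fixed deterministically (nonnegative loading sum) so
outputs are reproducible across linear-algebra backends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MethylationMatrix, ProbeAnnotation, SampleTable

__all__ = ["ControlPcs", "control_probe_pcs", "attach_technical_covariates"]


@dataclass
class ControlPcs:
    """Per-sample control-probe PC scores, in decreasing explained-variance
    order; ``scores`` is samples x n_pcs with columns ``pc1..pcK``."""

    scores: pd.DataFrame
    explained_variance: np.ndarray

    @property
    def n_pcs(self) -> int:
        return self.scores.shape[1]

    @property
    def sample_ids(self) -> list:
        return self.scores.index.tolist()


def control_probe_pcs(
    matrix: MethylationMatrix,
    annotation: ProbeAnnotation,
    n_pcs: int = 30,
    scale: bool = False,
) -> ControlPcs:
    """PCA of the (non-negative) control-probe submatrix.

    The submatrix is restricted to probes with ``control_type ==
    other_control``, centred probe-wise (optionally scaled), and decomposed
    by SVD.  Requests exceeding the matrix rank are reduced with a warning;
    zero-variance control probes are dropped with a warning.
    """
    ctrl = [p for p in annotation.control_probes(exclude_negative=True) if p in set(matrix.probe_ids)]
    if not ctrl:
        raise ValueError("no eligible control probes (control_type == 'other_control')")
    sub = matrix.beta.loc[ctrl].to_numpy(dtype=float)  # probes x samples
    sd = sub.std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"dropping {int((sd == 0).sum())} zero-variance control probes", stacklevel=2)
        keep = sd > 0
        sub, sd = sub[keep], sd[keep]
        if sub.shape[0] == 0:
            raise ValueError("all control probes have zero variance")
    centred = sub - sub.mean(axis=1, keepdims=True)
    if scale:
        centred = centred / sd[:, None]

    n_samples = sub.shape[1]
    max_pcs = min(sub.shape[0], n_samples - 1)
    if n_pcs > max_pcs:
        warnings.warn(f"requested {n_pcs} PCs but rank bound is {max_pcs}; reduced", stacklevel=2)
        n_pcs = max_pcs

    # SVD of probes x samples: right singular vectors are sample scores
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    k = n_pcs
    scores = vt[:k].T * s[:k]  # samples x k
    # deterministic sign: each PC's probe-loading vector sums nonnegative
    signs = np.where(u[:, :k].sum(axis=0) < 0, -1.0, 1.0)
    scores = scores * signs
    explained = (s[:k] ** 2) / (n_samples - 1)

    nonzero = explained > 1e-12 * max(explained[0], 1.0)
    scores, explained = scores[:, nonzero], explained[nonzero]
    cols = [f"pc{i + 1}" for i in range(scores.shape[1])]
    return ControlPcs(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=cols),
        explained_variance=explained,
    )


def attach_technical_covariates(table: SampleTable, pcs: ControlPcs) -> SampleTable:
    """Append PC scores as covariates ``pc1..pcK`` to the sample table.

    Sample sets must match exactly; attaching twice (duplicate covariate
    names) is an error.  Zero-variance PCs are never attached.
    """
    if set(table.sample_ids) != set(pcs.sample_ids):
        raise ValueError("sample ids of table and control PCs do not match")
    dup = [c for c in pcs.scores.columns if c in table.df.columns]
    if dup:
        raise ValueError(f"covariates already present: {dup}")
    keep = [c for c in pcs.scores.columns if pcs.scores[c].std() > 0]
    df = table.df.join(pcs.scores[keep].reindex(table.df.index))
    return SampleTable(df, dict(table.outcome_polarity))
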