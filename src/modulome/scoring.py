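"""Recovery scoring of a decomposition against planted synthetic truth.

Component identity is defined by content, never by index: recovered
components are matched to planted ones by maximizing total |Pearson r|
over an optimal one-to-one assignment (Hungarian algorithm), and member
sets are scored by F1 after the same matching.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .extraction import IModulon
from .ica import IcaDecomposition
from .synthetic import SyntheticTruth


def match_components(planted: pd.DataFrame, recovered: pd.DataFrame) -> pd.DataFrame:
    """Optimal one-to-one matching between planted (genes x modules) and
    recovered (genes x components) weight matrices by |Pearson r|.

    Returns one row per matched pair: planted id, recovered id, abs_r.
    Unmatched components (when counts differ) are simply absent.
    """
    if planted.shape[1] == 0 or recovered.shape[1] == 0:
        return pd.DataFrame(columns=["planted", "recovered", "abs_r"])
    P = planted.to_numpy(dtype=float)
    R = recovered.loc[planted.index].to_numpy(dtype=float)
    k_p, k_r = P.shape[1], R.shape[1]
    corr = np.zeros((k_p, k_r))
    for i in range(k_p):
        for j in range(k_r):
            with np.errstate(invalid="ignore"):
                c = np.corrcoef(P[:, i], R[:, j])[0, 1]
            corr[i, j] = abs(c) if np.isfinite(c) else 0.0
    ii, jj = linear_sum_assignment(-corr)
    return pd.DataFrame(
        {
            "planted": [planted.columns[i] for i in ii],
            "recovered": [recovered.columns[j] for j in jj],
            "abs_r": [corr[i, j] for i, j in zip(ii, jj)],
        }
    )


def membership_f1(true_members: set[str], predicted_members: set[str]) -> float:
    """F1 between a planted member set and an extracted one."""
    if not true_members and not predicted_members:
        return 1.0
    tp = len(true_members & predicted_members)
    if tp == 0:
        return 0.0
    precision = tp / len(predicted_members)
    recall = tp / len(true_members)
    return 2 * precision * recall / (precision + recall)


def score_recovery(
    truth: SyntheticTruth,
    dec: IcaDecomposition,
    ims: list[IModulon] | None = None,
) -> dict:
    """Mean matched |r| between planted and recovered components, plus
    (when extracted iModulons are supplied) mean membership F1 over the
    matched pairs."""
    matches = match_components(truth.planted_M, dec.M)
    out = {
        "matches": matches,
        "mean_abs_r": float(matches["abs_r"].mean()) if len(matches) else 0.0,
        "n_matched": int(len(matches)),
    }
    if ims is not None:
        by_id = {im.id: im for im in ims}
        f1s = []
        for row in matches.itertuples():
            im = by_id.get(row.recovered)
            truth_members = truth.modules[row.planted]
            f1s.append(membership_f1(truth_members, im.members if im else set()))
        out["membership_f1"] = float(np.mean(f1s)) if f1s else 0.0
        out["per_module_f1"] = dict(zip(matches["planted"], f1s))
    return out
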