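"""Template similarity as a pre-sorting "sortability" indicator.

Per-track templates T = [t_1, ..., t_n] and T-hat are compared with three
distances on the aligned 60-sample grid, without renormalization (the
distances stay in volts, the units of the data):

    MSE  = (1/n) * sum_i (t_i - that_i)^2
    MAE  = (1/n) * sum_i |t_i - that_i|
    RMSE = sqrt(MSE)

Small distances mean similar mean waveforms and predict poor sorting; for
recordings with more than two fibers the headline distance is the distance
of the *most similar* pair, which is flagged because it can misrepresent
multi-fiber recordings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocessing import ParameterError, Template

METRICS = ("mse", "mae", "rmse")


def template_distance(t: Template, t_hat: Template, metric: str = "rmse") -> float:
    """MSE, MAE or RMSE between two equal-length templates."""
    a = np.asarray(t.values, dtype=np.float64)
    b = np.asarray(t_hat.values, dtype=np.float64)
    if a.shape != b.shape:
        raise ParameterError(f"template length mismatch: {a.shape} vs {b.shape}")
    d = a - b
    if metric == "mse":
        return float(np.mean(d**2))
    if metric == "mae":
        return float(np.mean(np.abs(d)))
    if metric == "rmse":
        return float(np.sqrt(np.mean(d**2)))
    raise ParameterError(f"unknown metric {metric!r}; choose from {METRICS}")


def pairwise_distances(templates, metric: str = "rmse") -> pd.DataFrame:
    """Symmetric zero-diagonal distance matrix over a set of templates."""
    templates = list(templates)
    if len(templates) < 2:
        raise ParameterError("pairwise distances need at least 2 templates")
    tracks = [t.track for t in templates]
    if len(set(tracks)) != len(tracks):
        raise ParameterError("duplicate track labels among templates")
    n = len(templates)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = template_distance(templates[i], templates[j], metric)
    return pd.DataFrame(m, index=tracks, columns=tracks)


def most_similar_pair(matrix: pd.DataFrame):
    """Off-diagonal minimum of a distance matrix.

    Returns ``((track_a, track_b), distance)`` with ties broken by the
    lexicographically first track pair.
    """
    tracks = list(matrix.index)
    if len(tracks) < 2:
        raise ParameterError("need at least 2 templates")
    best = None
    for a, b in ((a, b) for i, a in enumerate(sorted(tracks))
                 for b in sorted(tracks)[i + 1:]):
        d = float(matrix.loc[a, b])
        if best is None or d < best[1]:
            best = ((a, b), d)
    return best


def sortability_table(templates_by_dataset: dict, reports) -> pd.DataFrame:
    """Join template distances with best supervised accuracy per recording.

    Parameters
    ----------
    templates_by_dataset : dict
        ``dataset id -> dict of track -> Template``.
    reports : iterable of EvalReport
        Supervised reports across feature sets for the same datasets.

    Returns one row per dataset: the minimum pairwise distance per metric
    (for >2 fibers this is the most-similar pair, flagged in
    ``reduced_to_pair``), the best mean CV accuracy over feature sets, the
    chance level 1/k and the fiber count.
    """
    rows = []
    by_ds: dict[str, list] = {}
    for r in reports:
        by_ds.setdefault(r.dataset, []).append(r)
    for ds, tmpl in sorted(templates_by_dataset.items()):
        if ds not in by_ds:
            raise ParameterError(f"no supervised reports for dataset {ds!r}")
        templates = list(tmpl.values())
        n_fibers = len(templates)
        row = {"dataset": ds, "n_fibers": n_fibers}
        for metric in METRICS:
            matrix = pairwise_distances(templates, metric)
            pair, dist = most_similar_pair(matrix)
            row[metric] = dist
        row["pair"] = "|".join(pair)
        row["reduced_to_pair"] = n_fibers > 2
        row["max_accuracy"] = max(r.accuracy for r in by_ds[ds])
        row["chance"] = 1.0 / n_fibers
        rows.append(row)
    return pd.DataFrame(rows)
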