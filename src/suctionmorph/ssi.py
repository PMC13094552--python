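"""The suction specialization index (SSI) and its variants.

For each taxon the index is the mean ordinal score over the ten
suction-related characters (``char_mean``; this is the SSI), reported
alongside the score sum (``char_sum``) and an *adjusted* SSI averaging
only the eight osteology/dentition characters — the fossil-visible subset,
excluding round mouth and throat grooves. The per-taxon sample standard
deviation (n-1 denominator) of the scores entering each mean is reported
for both character sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import CharacterMatrix, DataValidationError


def _row_stats(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-row (sum, mean, sample SD, n_used) over non-missing entries."""
    mask = np.isfinite(scores)
    n = mask.sum(axis=1)
    total = np.where(mask, scores, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, total / n, np.nan)
        dev2 = np.where(mask, (scores - mean[:, None]) ** 2, 0.0).sum(axis=1)
        sd = np.where(n > 1, np.sqrt(dev2 / np.maximum(n - 1, 1)), np.nan)
    return total, mean, sd, n


def compute_ssi(
    matrix: CharacterMatrix,
    policy: str = "renormalize",
    specialization_threshold: float | None = None,
) -> pd.DataFrame:
    """Compute the SSI table from a validated character matrix.

    Parameters
    ----------
    matrix
        Taxon x character ordinal scores; character class tags decide
        which columns enter the adjusted index.
    policy
        ``"renormalize"`` (default) averages over the non-missing
        characters of each taxon, recording ``n_used``; ``"error"``
        refuses matrices with missing scores.
    specialization_threshold
        If given, adds a boolean ``specialized`` column flagging taxa with
        ``char_mean`` strictly above the threshold (an SSI above 1.0 is
        conventionally read as strong evidence of suction specialization).

    Returns
    -------
    DataFrame indexed by taxon with columns ``char_sum``, ``char_mean``,
    ``adjusted_ssi``, ``score_sd``, ``adjusted_score_sd``, ``n_used``,
    ``n_used_adjusted``.
    """
    if policy not in ("error", "renormalize"):
        raise ValueError("policy must be 'error' or 'renormalize'")
    scores = matrix.scores
    if policy == "error" and not np.isfinite(scores).all():
        i, j = map(int, np.argwhere(~np.isfinite(scores))[0])
        raise DataValidationError(
            f"missing score for taxon {matrix.taxa[i]!r}, character "
            f"{matrix.characters[j].name!r} under policy='error'"
        )
    total, mean, sd, n = _row_stats(scores)
    if (n == 0).any():
        bad = matrix.taxa[int(np.flatnonzero(n == 0)[0])]
        raise DataValidationError(f"taxon {bad!r} has no usable character scores")

    osteo = matrix.osteo_dental_columns()
    a_total, a_mean, a_sd, a_n = _row_stats(scores[:, osteo])

    out = pd.DataFrame(
        {
            "char_sum": total,
            "char_mean": mean,
            "adjusted_ssi": a_mean,
            "score_sd": sd,
            "adjusted_score_sd": a_sd,
            "n_used": n,
            "n_used_adjusted": a_n,
        },
        index=pd.Index(matrix.taxa, name="taxon"),
    )
    if specialization_threshold is not None:
        out["specialized"] = out["char_mean"] > specialization_threshold
    return out


def rank_taxa(table: pd.DataFrame) -> list[str]:
    """Taxa ordered by decreasing SSI; ties broken alphabetically."""
    if table.empty:
        raise ValueError("SSI table is empty")
    return sorted(
        table.index, key=lambda t: (-table.at[t, "char_mean"], str(t).casefold())
    )
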