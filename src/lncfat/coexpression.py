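"""Expression correlation of cis pairs and the key-lncRNA / TF-pair selections.

Correlations are Pearson r over samples of log2(FPKM + 1), the same transform
the differential screen uses. With n = 6 samples r is a noisy statistic; no
significance filter is applied on it, only the strict thresholds below:

* key lncRNA: an FD-DEL with at least one cis target that is an FD-DEG and
  whose pair correlation exceeds 0.9;
* TF-target pair: binding score > 3 and pair correlation > 0.8.

Pairs in which either member has zero expression variance have undefined r;
they are emitted flagged and never selected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cis_targets import CisTargetLink
from .quant import ExpressionMatrix

__all__ = [
    "CoexpressionPair",
    "pearson_pairs",
    "select_key_lncrnas",
    "select_tf_deg_pairs",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoexpressionPair:
    lncrna_id: str  # or TF id for TF-gene pairs
    gene_id: str
    r: float  # NaN when undefined (zero-variance member)
    n_samples: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt((xc**2).sum()), np.sqrt((yc**2).sum())
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


def pearson_pairs(
    m: ExpressionMatrix,
    links: list[CisTargetLink] | list[tuple[str, str]],
    pseudocount: float = 1.0,
) -> list[CoexpressionPair]:
    """Pearson correlation on log2(FPKM + pseudocount) for each linked pair.

    ``links`` may be :class:`CisTargetLink` objects or plain (id_a, id_b)
    tuples. A link member absent from the matrix raises ``KeyError`` naming
    the id; zero-variance members yield r = NaN (flagged undefined).
    """
    x = m.log2_fpkm(pseudocount)
    pairs: list[CoexpressionPair] = []
    for link in links:
        a, b = (
            (link.lncrna_id, link.gene_id)
            if isinstance(link, CisTargetLink)
            else (link[0], link[1])
        )
        for ident in (a, b):
            if ident not in x.index:
                raise KeyError(f"feature {ident!r} missing from expression matrix")
        r = _pearson(x.loc[a].to_numpy(), x.loc[b].to_numpy())
        pairs.append(CoexpressionPair(a, b, r, x.shape[1]))
    return pairs


def select_key_lncrnas(
    pairs: list[CoexpressionPair],
    fd_dels: set[str],
    fd_degs: set[str],
    r_cut: float = 0.9,
) -> set[str]:
    """FD-DELs with an FD-DEG cis target correlated at r > ``r_cut`` (strict)."""
    keys = set()
    for p in pairs:
        if (
            p.defined
            and p.lncrna_id in fd_dels
            and p.gene_id in fd_degs
            and p.r > r_cut
        ):
            keys.add(p.lncrna_id)
    return keys


def select_tf_deg_pairs(
    pairs: list[CoexpressionPair],
    binding_scores: pd.Series | dict,
    score_cut: float = 3.0,
    r_cut: float = 0.8,
) -> list[CoexpressionPair]:
    """Keep TF-gene pairs with binding score > ``score_cut`` and r > ``r_cut``.

    ``binding_scores`` maps (tf_id, gene_id) to a binding score; pairs without
    a score are dropped with a warning.
    """
    scores = dict(binding_scores)
    kept, missing = [], 0
    for p in pairs:
        s = scores.get((p.lncrna_id, p.gene_id))
        if s is None:
            missing += 1
            continue
        if p.defined and s > score_cut and p.r > r_cut:
            kept.append(p)
    if missing:
        log.warning("%d TF-gene pairs dropped for missing binding scores", missing)
    return kept


def pairs_to_frame(pairs: list[CoexpressionPair], kept: set | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        [(p.lncrna_id, p.gene_id, p.r, p.n_samples) for p in pairs],
        columns=["id_a", "id_b", "r", "n_samples"],
    )
    if kept is not None:
        df["kept"] = [p.lncrna_id in kept for p in pairs]
    return df
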