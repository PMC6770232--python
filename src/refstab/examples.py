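"""Published worked-example data for the BestKeeper ranking rule.

A reference-gene survey of the shiitake mushroom *Lentinula edodes*
published per-gene BestKeeper summary statistics — the Ct standard
deviation ("std dev [± Ct]") and the Pearson correlation with the
BestKeeper index ("coeff. of corr. [R]") — for its ten pre-selected
candidates in four condition blocks, together with the final rank each
gene received.  The raw Ct measurements behind those summaries were
never deposited, but the summaries themselves are complete inputs for
the two-tier ranking rule, which reproduces every published rank
position; they therefore serve as the package's canonical worked
example and regression fixture for :func:`refstab.bestkeeper.bk_rank`.

Gene symbols use ASCII (``a-tub``/``b-tub`` for the tubulins).
"""

from __future__ import annotations

import pandas as pd

_GENES = ["Actin", "18S", "28S", "RPA12", "UBC", "UBI", "EF", "a-tub", "b-tub", "PPCI"]

_BLOCKS: dict[str, dict[str, list[float]]] = {
    "substrates": {
        "sd": [0.54, 0.35, 0.42, 0.39, 0.31, 0.48, 0.52, 0.52, 0.57, 0.39],
        "r": [0.998, 0.485, 0.965, 0.995, 0.897, 1.0, 0.977, 0.964, 0.997, 0.757],
        "published_rank": [6, 10, 2, 1, 8, 3, 4, 5, 7, 9],
    },
    "development": {
        "sd": [0.34, 0.92, 0.87, 0.42, 0.44, 0.72, 0.44, 0.68, 0.64, 0.57],
        "r": [0.994, 0.979, 0.995, 0.924, 0.947, 0.971, 0.806, 0.96, 0.994, 0.889],
        "published_rank": [1, 8, 7, 2, 3, 6, 10, 5, 4, 9],
    },
    "stresses": {
        "sd": [1.27, 0.86, 0.84, 0.95, 1.34, 1.33, 1.39, 1.17, 1.28, 0.93],
        "r": [0.999, 0.283, 0.998, 0.928, 0.964, 0.969, 0.986, 1.0, 0.992, 0.993],
        "published_rank": [5, 10, 1, 3, 8, 7, 9, 4, 6, 2],
    },
    "total": {
        "sd": [1.00, 0.94, 0.98, 0.78, 1.03, 1.19, 1.02, 1.11, 1.14, 0.85],
        "r": [0.957, 0.638, 0.967, 0.943, 0.973, 0.977, 0.954, 0.991, 0.991, 0.937],
        "published_rank": [4, 10, 3, 1, 6, 9, 5, 7, 8, 2],
    },
}


def lentinula_bestkeeper_summary(block: str | None = None) -> dict[str, pd.DataFrame]:
    """Published BestKeeper summaries for ten *L. edodes* candidates.

    Returns a dict of condition block → DataFrame indexed by gene with
    columns ``sd`` (Ct standard deviation), ``r`` (correlation with the
    BestKeeper index) and ``published_rank`` (the rank the survey
    assigned).  Pass ``block`` to get a single block's frame in a
    one-entry dict.  Blocks: ``substrates``, ``development``,
    ``stresses``, ``total``.
    """
    names = [block] if block is not None else list(_BLOCKS)
    out = {}
    for name in names:
        if name not in _BLOCKS:
            raise KeyError(f"unknown block {name!r}; have {list(_BLOCKS)}")
        out[name] = pd.DataFrame(_BLOCKS[name], index=pd.Index(_GENES, name="gene"))
    return out
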