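"""Deregression of EBVs with parent-average removal (Garrick-style).

BLUP shrinks an individual's EBV toward its parent average (PA), so records
whose EBV carries no own or progeny information contribute nothing beyond
their parents' genotypes to marker-model training.  Deregression back-solves
a 2 x 2 approximation of the evaluation equations for each individual,

    [ Z'PA Z_PA + 4L      -2L          ] [ PA  ]   [ y_PA    ]
    [ -2L                 Z'i Z_i + 2L ] [ EBV ] = [ y_i-PA  ]

with ``L = (1 - h2)/h2``, and information contents

    Z'PA Z_PA = L (0.5 a - 4) + 0.5 L sqrt(a^2 + 16/d)
    Z'i  Z_i  = d Z'PA Z_PA + 2 L (2 d - 1)

where ``a = 1 / (0.5 - r2_PA)`` and ``d = (0.5 - r2_PA) / (1 - r2_i)``.
``r2_PA = (r2_sire + r2_dam) / 4`` is the parent-average reliability and
``r2_i`` the individual's EBV reliability.  The deregressed value is
``DEBV = y_i-PA / Z'i Z_i``.

Individuals whose reliability does not exceed their parent-average
reliability carry no own information; their information content is
non-positive and the record is flagged non-deregressable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "DeregressionRecord",
    "parent_average_reliability",
    "ebv_reliability",
    "deregress",
    "deregress_population",
]

logger = logging.getLogger(__name__)

RELIABILITY_MARGIN = 1e-6  # r2_i must exceed r2_PA by this to deregress


@dataclass
class DeregressionRecord:
    """Intermediate quantities and the deregressed value for one individual."""

    id: str
    pa: float
    ebv: float
    r2_pa: float
    r2_i: float
    lam: float
    alpha: float
    delta: float
    info_pa: float       # Z'PA Z_PA
    info_i: float        # Z'i-PA Z_i-PA
    y_i_pa: float        # right-hand side, individual row
    debv: float
    deregressable: bool = True


def parent_average_reliability(r2_sire: float, r2_dam: float) -> float:
    """Reliability of the parent average: ``(r2_sire + r2_dam) / 4``.

    An unknown parent contributes reliability 0.
    """
    for v in (r2_sire, r2_dam):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"parent reliability outside [0, 1]: {v}")
    return (r2_sire + r2_dam) / 4.0


def ebv_reliability(pev: float, f: float, sigma_a2: float) -> float:
    """EBV reliability ``r2_i = 1 - s2_i / ((1 + f_i) sigma_A^2)``, floored at 0."""
    if sigma_a2 <= 0:
        raise ValueError("sigma_a2 must be positive")
    r2 = 1.0 - pev / ((1.0 + f) * sigma_a2)
    if r2 < 0:
        logger.info("ebv_reliability: PEV exceeds additive variance; floored at 0")
        return 0.0
    return r2


def deregress(pa: float, ebv: float, r2_pa: float, r2_i: float, h2: float,
              id: str = "") -> DeregressionRecord:
    """Deregress one EBV, removing the parent-average contribution.

    Raises on invalid reliabilities or heritability; returns a record flagged
    ``deregressable=False`` (with ``debv = nan``) when the individual's own
    information content is non-positive.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be in (0, 1)")
    if r2_pa >= 0.5:
        raise ValueError("parent-average reliability must be < 0.5")
    if r2_i >= 1.0:
        raise ValueError("EBV reliability must be < 1")
    lam = (1.0 - h2) / h2
    alpha = 1.0 / (0.5 - r2_pa)
    delta = (0.5 - r2_pa) / (1.0 - r2_i)
    info_pa = lam * (0.5 * alpha - 4.0) + 0.5 * lam * math.sqrt(alpha**2 + 16.0 / delta)
    info_i = delta * info_pa + 2.0 * lam * (2.0 * delta - 1.0)
    y_i_pa = -2.0 * lam * pa + (info_i + 2.0 * lam) * ebv
    if info_i <= 0 or r2_i <= r2_pa + RELIABILITY_MARGIN:
        return DeregressionRecord(
            id=str(id), pa=pa, ebv=ebv, r2_pa=r2_pa, r2_i=r2_i, lam=lam,
            alpha=alpha, delta=delta, info_pa=info_pa, info_i=info_i,
            y_i_pa=y_i_pa, debv=float("nan"), deregressable=False,
        )
    return DeregressionRecord(
        id=str(id), pa=pa, ebv=ebv, r2_pa=r2_pa, r2_i=r2_i, lam=lam,
        alpha=alpha, delta=delta, info_pa=info_pa, info_i=info_i,
        y_i_pa=y_i_pa, debv=y_i_pa / info_i, deregressable=True,
    )


def deregress_population(
    evaluation,
    pedigree: Pedigree,
    ids=None,
    h2: float | None = None,
) -> pd.DataFrame:
    """Deregress every (genotyped) individual of an evaluation.

    Parameters
    ----------
    evaluation
        :class:`treegs.ablup.EvaluationResult` providing EBVs and
        reliabilities for individuals and their parents.
    pedigree
        Source of the parent map; unknown parents contribute EBV 0 and
        reliability 0 to the parent average.
    ids
        Subset to deregress (default: all pedigree members).
    h2
        Heritability used for ``lambda``; defaults to the evaluation's h2.

    Returns
    -------
    DataFrame
        One row per individual with all :class:`DeregressionRecord` fields.
        Non-deregressable individuals have ``debv = NaN`` and
        ``deregressable = False``; their count is logged.
    """
    h2 = evaluation.h2 if h2 is None else h2
    tab = evaluation.table.set_index("id")
    if ids is None:
        ids = list(tab.index)
    if not 0.0 < h2 < 1.0:
        logger.warning(
            "deregress_population: heritability %.3g outside (0, 1); "
            "no record is deregressable", h2,
        )
        return pd.DataFrame([
            DeregressionRecord(
                id=str(i), pa=np.nan, ebv=tab.at[str(i), "ebv"], r2_pa=np.nan,
                r2_i=np.nan, lam=np.nan, alpha=np.nan, delta=np.nan,
                info_pa=np.nan, info_i=np.nan, y_i_pa=np.nan, debv=np.nan,
                deregressable=False,
            ).__dict__
            for i in ids
        ])
    parent_map = pedigree.parent_map()
    records = []
    missing_parent_rel = 0
    for i in (str(x) for x in ids):
        ebv = tab.at[i, "ebv"]
        r2_i = min(tab.at[i, "reliability"], 1.0 - 1e-9)
        sire, dam = parent_map.get(i, (None, None))
        pa_parts, r2_parents = [], []
        for p in (sire, dam):
            if p is None or p not in tab.index:
                pa_parts.append(0.0)
                r2_parents.append(0.0)
                if p is not None:
                    missing_parent_rel += 1
            else:
                pa_parts.append(tab.at[p, "ebv"])
                r2_parents.append(min(tab.at[p, "reliability"], 1.0))
        pa = 0.5 * (pa_parts[0] + pa_parts[1])
        r2_pa = min(parent_average_reliability(*r2_parents), 0.5 - 1e-9)
        records.append(deregress(pa, ebv, r2_pa, r2_i, h2, id=i))
    if missing_parent_rel:
        logger.warning(
            "deregress_population: %d parents lacked reliabilities; treated as 0",
            missing_parent_rel,
        )
    df = pd.DataFrame([r.__dict__ for r in records])
    n_bad = int((~df["deregressable"]).sum())
    if n_bad:
        logger.info("deregress_population: %d records not deregressable", n_bad)
    return df
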