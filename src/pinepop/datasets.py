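"""Published observed data bundled for worked examples and validation.

Two small tables from the loblolly pine (Pinus taeda) candidate-gene survey,
with Scots pine (P. sylvestris) as outgroup:

* the per-locus polymorphism-category counts (exclusive to either species,
  shared, fixed) for the 27 loci with outgroup data, together with sample
  sizes — 27-32 loblolly megagametophytes per locus (32 used where the exact
  value is unreported) and one or two Scots pine gametes.  Loci recorded
  with zero outgroup-exclusive and zero shared expectations in the published
  per-locus analysis had a single outgroup gamete; ``n2`` encodes that.
* the printed observed/expected quadruplets and G statistics for the six
  loci that deviated significantly from the fitted isolation model, used as
  worked-example checks of the G-test arithmetic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .locus_io import IMCounts

__all__ = ["pine_im_counts", "pine_im_significant_rows"]

# locus, S_x1, S_x2, S_shared, S_fixed, n1, n2
_IM_ROWS = [
    ("4cl", 11, 2, 0, 2, 32, 2),
    ("axr", 1, 2, 0, 13, 32, 2),
    ("bhlh62-like", 7, 0, 0, 3, 32, 2),
    ("ccoaoemt", 14, 0, 0, 10, 32, 1),
    ("cesA3", 4, 0, 0, 4, 32, 2),
    ("cyp450-like", 10, 0, 0, 0, 32, 1),
    ("enth1-like", 11, 0, 0, 7, 32, 2),
    ("erd3", 8, 0, 0, 22, 32, 1),
    ("erebp-like", 22, 1, 0, 24, 32, 2),
    ("erf1-like", 6, 0, 0, 14, 32, 1),
    ("gatabp1", 0, 1, 0, 29, 32, 2),
    ("gatabp2", 11, 3, 0, 12, 32, 2),
    ("ldox-a", 14, 3, 0, 7, 32, 2),
    ("ldox-c", 18, 0, 0, 12, 32, 1),
    ("lp5", 20, 2, 4, 1, 32, 2),
    ("mybs3-like", 5, 0, 0, 5, 32, 1),
    ("myb3-psd", 11, 1, 0, 17, 32, 2),
    ("nac1", 19, 1, 0, 12, 32, 2),
    ("pal1", 6, 5, 0, 6, 32, 2),
    ("pcna", 16, 0, 0, 2, 32, 2),
    ("pr4.1", 18, 4, 1, 15, 32, 2),
    ("rd21a", 25, 0, 0, 17, 32, 1),
    ("sams2", 6, 8, 0, 0, 32, 2),
    ("set-like-b", 6, 8, 0, 11, 32, 2),
    ("set-like-c", 19, 18, 0, 1, 32, 2),
    ("tps-like", 12, 3, 0, 11, 32, 2),
    ("wrky-like-1", 7, 1, 2, 1, 32, 2),
]

# printed observed and expected quadruplets, G and p for the six loci that
# rejected the isolation model (Bonferroni alpha = 0.05)
_SIG_ROWS = [
    ("axr", (1, 2, 0, 13), (7.71, 2.25, 0.25, 5.65), 17.08, 1.84e-3),
    ("gatabp1", (0, 1, 0, 29), (8.34, 2.39, 0.27, 6.00), 89.62, 1.6e-18),
    ("lp5", (20, 2, 4, 1), (13.25, 3.80, 0.42, 9.53), 27.39, 1.7e-5),
    ("pcna", (16, 0, 0, 2), (8.83, 2.53, 0.28, 6.36), 14.38, 6.2e-3),
    ("sams2", (6, 8, 0, 0), (6.87, 1.97, 0.22, 4.94), 20.81, 3.5e-4),
    ("set-like-c", (19, 18, 0, 1), (18.65, 5.34, 0.59, 13.42), 39.26, 6.2e-8),
]


def pine_im_counts(uniform_n2: bool = False) -> pd.DataFrame:
    """Polymorphism-category counts for the 27 pine loci with outgroup data.

    Columns: locus, S_x1, S_x2, S_shared, S_fixed, n1, n2.  With
    ``uniform_n2=True`` every locus is reported as having two outgroup
    gametes (the coarser assumption used when per-locus outgroup sampling
    is ignored).
    """
    df = pd.DataFrame(
        _IM_ROWS, columns=["locus", "S_x1", "S_x2", "S_shared", "S_fixed", "n1", "n2"]
    )
    if uniform_n2:
        df["n2"] = 2
    return df


def pine_im_significant_rows() -> pd.DataFrame:
    """Printed per-locus isolation-model results for the six significant loci
    (observed and expected quadruplets, G statistic and p-value)."""
    rows = []
    for locus, obs, exp, g, p in _SIG_ROWS:
        rows.append(
            {
                "locus": locus,
                "observed": np.asarray(obs, dtype=float),
                "expected": np.asarray(exp, dtype=float),
                "G": g,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def pine_im_counts_objects(uniform_n2: bool = False) -> tuple[list[IMCounts], list[int], list[int]]:
    """The same table as (IMCounts list, n1 list, n2 list)."""
    df = pine_im_counts(uniform_n2=uniform_n2)
    counts = [
        IMCounts(r.locus, int(r.S_x1), int(r.S_x2), int(r.S_shared), int(r.S_fixed))
        for r in df.itertuples()
    ]
    return counts, df["n1"].tolist(), df["n2"].tolist()
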