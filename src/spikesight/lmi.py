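"""Learning modulation index (LMI) and the excitation-inhibition balance
summary.

For each cortical area ``a`` and cell class ``cc`` (RS or FS), the LMI is
the normalized difference of the grand-average whisker-evoked rate change
(delta-AP, relative to the pre-whisker baseline) between Expert and Novice
mice:

    LMI_cc,a = (dAP_Expert - dAP_Novice) / (|dAP_Expert| + |dAP_Novice|)

Positive values indicate increased evoked activity after learning.  The
change in the putative excitation-inhibition balance of an area is
summarized as ``LMI_RS - LMI_FS``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .modulation import EvokedResponse


@dataclass
class LMIRecord:
    area: str
    cell_class: str
    delta_ap_novice_hz: float
    delta_ap_expert_hz: float
    lmi: float
    n_novice: int = 0
    n_expert: int = 0


@dataclass
class EIBalanceRecord:
    area: str
    ei_lmi: float  # LMI_RS - LMI_FS, in [-2, 2]


def learning_modulation_index(delta_ap_expert: float,
                              delta_ap_novice: float) -> float:
    """LMI of one area x class from the two grand-average evoked deltas.

    Lies in [-1, 1]; undefined (NaN, with a warning) when both deltas are
    zero.  |LMI| = 1 exactly when the deltas have opposite signs or one is
    zero.
    """
    denom = abs(delta_ap_expert) + abs(delta_ap_novice)
    if denom == 0:
        warnings.warn("LMI undefined: both evoked deltas are zero",
                      stacklevel=2)
        return math.nan
    return (delta_ap_expert - delta_ap_novice) / denom


def ei_balance(lmi_rs: float, lmi_fs: float) -> float:
    """Excitation-inhibition balance change: LMI_RS - LMI_FS."""
    if math.isnan(lmi_rs) or math.isnan(lmi_fs):
        return math.nan
    return lmi_rs - lmi_fs


def lmi_table(novice_responses: Sequence[EvokedResponse],
              expert_responses: Sequence[EvokedResponse]
              ) -> tuple[list[LMIRecord], list[EIBalanceRecord]]:
    """Grand-average evoked deltas per area x class in each group, then the
    LMI per area x class and the E-I balance per area.

    Units are pooled across mice within each group (grand average).  Areas
    or classes present in only one group are skipped with a warning.
    """

    def grand(responses):
        df = pd.DataFrame([{"area": r.area, "cell_class": r.cell_class,
                            "delta": r.delta_rate_hz} for r in responses])
        if df.empty:
            raise AnalysisError("lmi_table: a group has no evoked responses")
        return df.groupby(["area", "cell_class"])["delta"].agg(["mean", "size"])

    gn, ge = grand(novice_responses), grand(expert_responses)
    records: list[LMIRecord] = []
    for key in sorted(set(gn.index) | set(ge.index)):
        if key not in gn.index or key not in ge.index:
            warnings.warn(f"area/class {key} present in only one group; "
                          f"skipped", stacklevel=2)
            continue
        area, cls = key
        dn = float(gn.loc[key, "mean"])
        de = float(ge.loc[key, "mean"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lmi = learning_modulation_index(de, dn)
        records.append(LMIRecord(area=area, cell_class=cls,
                                 delta_ap_novice_hz=dn, delta_ap_expert_hz=de,
                                 lmi=lmi,
                                 n_novice=int(gn.loc[key, "size"]),
                                 n_expert=int(ge.loc[key, "size"])))

    balances: list[EIBalanceRecord] = []
    by_area: dict[str, dict[str, float]] = {}
    for r in records:
        by_area.setdefault(r.area, {})[r.cell_class] = r.lmi
    for area, classes in sorted(by_area.items()):
        if "RS" in classes and "FS" in classes:
            balances.append(EIBalanceRecord(
                area=area, ei_lmi=ei_balance(classes["RS"], classes["FS"])))
    return records, balances


def lmi_frame(records: Sequence[LMIRecord]) -> pd.DataFrame:
    """LMI records as a table, indices rounded to two decimals for output."""
    return pd.DataFrame(
        [{"area": r.area, "cell_class": r.cell_class,
          "delta_ap_novice_hz": r.delta_ap_novice_hz,
          "delta_ap_expert_hz": r.delta_ap_expert_hz,
          "lmi": round(r.lmi, 2) if not math.isnan(r.lmi) else math.nan,
          "n_novice": r.n_novice, "n_expert": r.n_expert}
         for r in records])
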