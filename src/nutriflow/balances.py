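"""Foreign-fishing and trade balances per nation and nutrient.

For nation *i* and nutrient *n*, in RNI-equivalents:

    FFB_in = FF_in − LossFF_in
    TB_in  = IMP_in − EXP_in

FF is the nation's own fleet fishing other EEZs, plus the high seas when
the high-seas toggle is on (the EEZ-only variant contrasts nations whose
gains rely on high-seas access).  LossFF is extraction from the nation's
EEZ by other nations' fleets.  A positive TB means the country is a net
importer of nutrient *n*.  The across-nutrient mean is the unweighted
arithmetic mean over the seven per-nutrient balances.
"""

from __future__ import annotations

import pandas as pd

from .accounting import NutrientLedger
from .nutrients import NUTRIENTS

QUADRANTS = ("gain_both", "gain_ff_only", "gain_trade_only", "loss_both")


def foreign_fishing_balance(
    ledger: NutrientLedger, include_high_seas: bool = True
) -> pd.DataFrame:
    """FFB per nation (rows) and nutrient (columns), in RNI-equivalents."""
    ff = ledger.channel("ff_eez")
    if include_high_seas:
        ff = ff + ledger.channel("ff_hs")
    return ff - ledger.channel("loss_ff")


def trade_balance(ledger: NutrientLedger) -> pd.DataFrame:
    """TB per nation and nutrient, in RNI-equivalents."""
    return ledger.channel("imported") - ledger.channel("exported")


def balance_table(
    ledger: NutrientLedger, include_high_seas: bool = True
) -> pd.DataFrame:
    """Tidy per-nation balance table with per-nutrient rows plus a "mean" row.

    Columns: nation, nutrient, ffb, tb, include_high_seas, foc_adjusted.
    """
    ffb = foreign_fishing_balance(ledger, include_high_seas)
    tb = trade_balance(ledger)
    long = (
        pd.concat(
            {"ffb": ffb.stack(), "tb": tb.stack()}, axis=1
        )
        .rename_axis(["nation", "nutrient"])
        .reset_index()
    )
    mean = (
        long.groupby("nation")[["ffb", "tb"]].mean().reset_index()
        .assign(nutrient="mean")
    )
    out = pd.concat([long, mean], ignore_index=True)
    out["include_high_seas"] = include_high_seas
    out["foc_adjusted"] = ledger.foc_mode
    cat = pd.CategoricalDtype(list(NUTRIENTS) + ["mean"], ordered=True)
    out["nutrient"] = out["nutrient"].astype(cat)
    return out.sort_values(["nation", "nutrient"]).reset_index(drop=True)


def classify_nation(ffb_mean: float, tb_mean: float) -> tuple[str, str]:
    """Quadrant label and net sign from the across-nutrient mean balances.

    Exact zeros classify as gains (documented tie rule); the net sign is
    the sign of ffb + tb, zero counting as positive.
    """
    ff_gain = ffb_mean >= 0
    tr_gain = tb_mean >= 0
    quadrant = {
        (True, True): "gain_both",
        (True, False): "gain_ff_only",
        (False, True): "gain_trade_only",
        (False, False): "loss_both",
    }[(ff_gain, tr_gain)]
    net = "positive" if ffb_mean + tb_mean >= 0 else "negative"
    return quadrant, net


def classification_table(balances: pd.DataFrame) -> pd.DataFrame:
    """Quadrant/net-sign classification for every nation's mean balances."""
    mean = balances[balances["nutrient"] == "mean"]
    rows = [
        (r.nation, *classify_nation(r.ffb, r.tb), r.ffb, r.tb)
        for r in mean.itertuples()
    ]
    return pd.DataFrame(
        rows, columns=["nation", "quadrant", "net", "ffb_mean", "tb_mean"]
    )
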