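"""The ecosystem capability account.

Combines the three accounts into a single "ecological currency":

* ECU_P = (CIUV + W15 + EIIUV) / 3, the mean internal unit value per SELU;
* capabilities = accessible resource x ECU_P for carbon (C10, tC), water
  (W6, 1000 m3) and infrastructure (adjusted TEIP, index-ha);
* TEC = carbon + water + infrastructure capability, summed over SELUs;
* the inter-date TEC difference is an ecological debt (negative) or
  credit (positive).

All multiplications chain at full precision: 2-decimal index values are a
presentation concern only. The infrastructure internal unit value is
computed once from the inter-date infrastructure account and used for both
the opening and closing ECU_P.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError


def ecu_average(ciuv, w15, eiiuv):
    """ECU_P: arithmetic mean of the three internal unit values."""
    vals = [np.asarray(v, dtype=float) for v in (ciuv, w15, eiiuv)]
    for v in vals:
        if np.any((v < 0) | (v > 1)):
            raise DomainError("internal unit values must lie in [0, 1]")
    out = sum(vals) / 3.0
    return float(out) if np.ndim(out) == 0 else out


def capabilities(c10, w6, teip_adj, ecu_p):
    """(C_EC, W_EC, EI_EC, TEC): resources scaled by the mean unit value."""
    c10 = np.asarray(c10, dtype=float)
    w6 = np.asarray(w6, dtype=float)
    teip = np.asarray(teip_adj, dtype=float)
    if np.any(c10 < 0) or np.any(teip < 0):
        raise DomainError("resources must be non-negative")
    c_ec = c10 * ecu_p
    w_ec = w6 * ecu_p
    ei_ec = teip * ecu_p
    return c_ec, w_ec, ei_ec, c_ec + w_ec + ei_ec


def ecological_balance(tec_open, tec_close):
    """(delta, percent, label) of the inter-date TEC change.

    ``percent`` is 100 x delta / TEC_open rounded to the nearest integer;
    the label is "debt" for a loss, "credit" for a gain, "balanced" for no
    change. A zero opening TEC leaves the percentage undefined (None).
    """
    tec_open = float(tec_open)
    tec_close = float(tec_close)
    delta = tec_close - tec_open
    percent = None if tec_open == 0 else int(np.rint(100.0 * delta / tec_open))
    label = "debt" if delta < 0 else ("credit" if delta > 0 else "balanced")
    return delta, percent, label


def assemble_capability(
    carbon_acct: pd.DataFrame,
    water_acct: pd.DataFrame,
    infra_acct: pd.DataFrame,
    teip_row: str,
) -> pd.DataFrame:
    """Per-date capability table from the three assembled accounts.

    ``teip_row`` names the adjusted-TEIP row to use ("TEIP1_adj" for the
    opening date, "TEIP2_adj" for the closing date). SELU columns are taken
    from the carbon account; the water and infrastructure accounts must
    share them.
    """
    selus = [c for c in carbon_acct.columns if c != "Total"]
    c10 = carbon_acct.loc["C10", selus].astype(float)
    ciuv = carbon_acct.loc["CIUV", selus].astype(float)
    w6 = water_acct.loc["W6", selus].astype(float)
    w15 = water_acct.loc["W15", selus].astype(float)
    teip = infra_acct.loc[teip_row, selus].astype(float)
    eiiuv = infra_acct.loc["EIIUV", selus].astype(float)

    ecu_p = ecu_average(ciuv, w15, eiiuv)
    c_ec, w_ec, ei_ec, tec = capabilities(c10, w6, teip, ecu_p)
    table = pd.DataFrame(
        {
            "C10": c10, "CIUV": ciuv,
            "W6": w6, "W15": w15,
            "TEIP_adj": teip, "EIIUV": eiiuv,
            "ECU_P": ecu_p,
            "C_EC": c_ec, "W_EC": w_ec, "EI_EC": ei_ec, "TEC": tec,
        }
    ).T
    table["Total"] = table.loc[["C10", "W6", "TEIP_adj", "C_EC", "W_EC", "EI_EC", "TEC"]].sum(
        axis=1
    ).reindex(table.index)
    return table


def balance_table(cap_open: pd.DataFrame, cap_close: pd.DataFrame) -> pd.DataFrame:
    """Inter-date difference table: delta TEC, integer percent, label."""
    cols = cap_open.columns
    delta = cap_close.loc["TEC", cols] - cap_open.loc["TEC", cols]
    percent = []
    labels = []
    for c in cols:
        d, p, lab = ecological_balance(cap_open.loc["TEC", c], cap_close.loc["TEC", c])
        percent.append(p)
        labels.append(lab)
    return pd.DataFrame(
        {"TEC_close - TEC_open": delta, "Percentage": percent, "Balance": labels}
    ).T
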