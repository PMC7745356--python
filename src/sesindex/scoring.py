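"""Apply a scoring table to respondent data and summarize by site.

A respondent's sum score is the count of owned items over their site's
index items; the SES score is a table lookup. Respondents missing any
design item are flagged unscorable and excluded from summaries (with an
explicit count), never imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import ResponseDataset
from .index import ScoringTable


class UnknownSiteError(KeyError):
    """A respondent's site has no column in the scoring table."""


def score_dataset(table: ScoringTable, data: ResponseDataset) -> pd.DataFrame:
    """Score every respondent through their site's table column.

    Returns one row per respondent: id, site, sum_score (nullable int),
    ses_score (NaN when unscorable), and an ``unscorable`` flag.
    """
    unknown = set(data.sites) - set(table.sites)
    if unknown:
        raise UnknownSiteError(f"sites absent from scoring table: {sorted(unknown)}")

    ids = data.data["id"] if "id" in data.data.columns else pd.Series(
        np.arange(1, len(data) + 1), name="id"
    )
    out = pd.DataFrame({"id": ids.to_numpy(), "site": data.data["site"].to_numpy()})
    sum_scores = np.full(len(data), np.nan)
    ses = np.full(len(data), np.nan)
    for site in data.sites:
        rows = (out["site"] == site).to_numpy()
        items = table.site_items[site]
        X = data.data.loc[rows, items].to_numpy(dtype=float)
        complete = ~np.isnan(X).any(axis=1)
        s = X[complete].sum(axis=1).astype(int)
        idx = np.flatnonzero(rows)[complete]
        sum_scores[idx] = s
        ses[idx] = table.scores[site][s]
    out["sum_score"] = pd.array(sum_scores, dtype="Int64")
    out["ses_score"] = ses
    out["unscorable"] = np.isnan(ses)
    return out


def site_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/n of SES scores per site plus a pooled row.

    Unscorable respondents are excluded; their count is reported in the
    ``n_unscorable`` column.
    """
    rows = []
    for site, grp in scores.groupby("site", sort=False):
        valid = grp.loc[~grp["unscorable"], "ses_score"]
        rows.append(
            {"site": site, "n": int(valid.size),
             "n_unscorable": int(grp["unscorable"].sum()),
             "mean": valid.mean(), "sd": valid.std(ddof=1)}
        )
    valid = scores.loc[~scores["unscorable"], "ses_score"]
    rows.append(
        {"site": "(pooled)", "n": int(valid.size),
         "n_unscorable": int(scores["unscorable"].sum()),
         "mean": valid.mean(), "sd": valid.std(ddof=1)}
    )
    return pd.DataFrame(rows)
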