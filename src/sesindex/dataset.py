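"""Respondent-level response data container.

A :class:`ResponseDataset` wraps a pandas DataFrame holding one row per
respondent: a site label, dichotomous item columns (0/1 with NaN for
missing), optional covariate columns, and — for synthetic cohorts only —
the generating latent trait ``theta`` retained for recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: covariate columns a dataset may carry (all optional)
COVARIATE_COLUMNS = (
    "education_type",
    "education_years_band",
    "antenatal_care",
    "facility_delivery",
)

EDUCATION_BANDS = ("0", "1-6", "7-12", "13+")


class DatasetError(ValueError):
    """Raised when a response table violates the dataset contract."""


@dataclass
class ResponseDataset:
    """Respondents x items binary matrix with site labels and covariates.

    Parameters
    ----------
    data:
        One row per respondent. Must contain ``site`` plus every column in
        ``items``. Item values must be 0, 1 or missing (NaN).
    items:
        Names of the item columns, in order.
    """

    data: pd.DataFrame
    items: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "site" not in self.data.columns:
            raise DatasetError("response data must have a 'site' column")
        missing = [c for c in self.items if c not in self.data.columns]
        if missing:
            raise DatasetError(f"item columns absent from data: {missing}")
        block = self.data[self.items].to_numpy(dtype=float)
        bad = ~(np.isnan(block) | (block == 0) | (block == 1))
        if bad.any():
            raise DatasetError("item values must be 0, 1 or missing")

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def sites(self) -> list[str]:
        return list(pd.unique(self.data["site"]))

    def item_matrix(self, items: list[str] | None = None) -> np.ndarray:
        """Item block as a float array with NaN marking missing responses."""
        return self.data[items or self.items].to_numpy(dtype=float)

    def observed_mask(self, items: list[str] | None = None) -> np.ndarray:
        return ~np.isnan(self.item_matrix(items))

    def complete_mask(self, items: list[str] | None = None) -> np.ndarray:
        """Boolean row mask of respondents with no missing item responses."""
        return self.observed_mask(items).all(axis=1)

    def for_site(self, site: str) -> "ResponseDataset":
        sub = self.data[self.data["site"] == site].reset_index(drop=True)
        if sub.empty:
            raise DatasetError(f"no respondents for site {site!r}")
        return ResponseDataset(sub, list(self.items))

    def prevalences(self, site: str | None = None) -> pd.Series:
        """Observed endorsement fraction per item (NaN-aware)."""
        frame = self.data if site is None else self.data[self.data["site"] == site]
        return frame[self.items].mean()

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, items: list[str] | None = None) -> "ResponseDataset":
        frame = pd.read_csv(path)
        if items is None:
            reserved = {"id", "site", "theta", *COVARIATE_COLUMNS}
            items = [c for c in frame.columns if c not in reserved]
        return cls(frame, list(items))
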