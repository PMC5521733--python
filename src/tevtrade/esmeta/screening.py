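"""Record screening: which valuation observations enter the meta-analysis.

The screening rules mirror the independence and completeness requirements of
the valuation-database extraction: benefit-transfer-derived studies are
dropped (not independent), as are records without a specific location,
without an identified ES type or valuation method, and net-present-value
records that lack the discount rate or horizon needed to annualize them.
NPV records that do carry both are converted to an annual flow with the
annuity factor before inclusion.  Each rule can be toggled; a screening
report counts removals per rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..carbonval import annualize
from ..exceptions import ScreeningError

__all__ = ["ScreeningRules", "ScreeningReport", "screen_records"]


@dataclass
class ScreeningRules:
    drop_benefit_transfer: bool = True
    require_location: bool = True
    require_es_type: bool = True
    require_method: bool = True
    drop_npv_without_rate: bool = True
    annualize_npv: bool = True

    def all_disabled(self) -> bool:
        return not any([self.drop_benefit_transfer, self.require_location,
                        self.require_es_type, self.require_method,
                        self.drop_npv_without_rate, self.annualize_npv])


@dataclass
class ScreeningReport:
    removed: dict[str, int] = field(default_factory=dict)
    n_in: int = 0
    n_out: int = 0
    n_annualized: int = 0

    def summary(self) -> str:
        parts = [f"{self.n_in} records in, {self.n_out} kept, "
                 f"{self.n_annualized} NPVs annualized"]
        for rule, count in self.removed.items():
            parts.append(f"  removed by {rule}: {count}")
        return "\n".join(parts)


def screen_records(raw_records: pd.DataFrame,
                   rules: ScreeningRules | None = None,
                   ) -> tuple[pd.DataFrame, ScreeningReport]:
    """Apply the enabled screening rules and annualize NPV records."""
    rules = rules or ScreeningRules()
    records = raw_records.copy().reset_index(drop=True)
    report = ScreeningReport(n_in=len(records))

    def drop(mask: np.ndarray, rule: str) -> None:
        nonlocal records
        count = int(mask.sum())
        if count:
            records = records.loc[~mask].reset_index(drop=True)
        report.removed[rule] = count

    def flag(col: str, default: bool) -> np.ndarray:
        if col not in records.columns:
            return np.full(len(records), default)
        return records[col].fillna(default).to_numpy(dtype=bool)

    if rules.drop_benefit_transfer:
        drop(flag("benefit_transfer", False), "benefit_transfer")
    if rules.require_location:
        drop(~flag("has_location", True), "no_location")
    if rules.require_es_type:
        drop(~flag("has_es_type", True), "no_es_type")
    if rules.require_method:
        drop(~flag("has_method", True), "no_method")
    if rules.drop_npv_without_rate:
        is_npv = flag("is_npv", False)
        has_info = (records.get("discount_rate", pd.Series(dtype=float))
                    .notna().to_numpy(dtype=bool)
                    & records.get("horizon", pd.Series(dtype=float))
                    .notna().to_numpy(dtype=bool)) if len(records) else np.array([], bool)
        drop(is_npv & ~has_info, "npv_without_rate")

    if rules.annualize_npv and len(records):
        is_npv = flag("is_npv", False)
        idx = np.flatnonzero(is_npv)
        for i in idx:
            row = records.iloc[i]
            records.loc[records.index[i], "value"] = annualize(
                float(row["value"]), float(row["discount_rate"]),
                float(row["horizon"]))
        records.loc[records.index[idx], "is_npv"] = False
        report.n_annualized = len(idx)
        records["log_value"] = np.log(records["value"].to_numpy(dtype=float))

    if len(records) == 0:
        raise ScreeningError("no records survive screening")
    report.n_out = len(records)
    return records, report
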