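"""Packaged reference data.

One small table ships with the package: group-mean FA measurements of
Yakutian steppe-meadow pasture grasses before and after mowing (n = 4 per
period), on two bases — absolute content in mg/g dry weight and percent of
total FA — with SEMs and "trace" literals exactly as printed in the source
measurement table.  The printed class rows (SFA, UFA, Total FA) are kept
as data alongside the per-FA rows: printed sums reflect the underlying
per-sample values and can differ from recomputed column sums in the last
decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .profiles import Basis, FAProfile

__all__ = ["PastureMowingTable", "load_pasture_mowing"]


@dataclass(frozen=True)
class PastureMowingTable:
    """Pasture-grass FA table split into per-FA rows and printed sums."""

    fa: pd.DataFrame        # per-FA rows, indexed by label; NaN where "trace"
    printed: pd.DataFrame   # printed SFA / UFA / Total FA rows as data
    n_before: int = 4
    n_after: int = 4

    def profile(self, period: str, basis: Basis | str) -> FAProfile:
        """Group-mean profile for ``period`` in {"before", "after"}.

        Trace entries carry amount 0 and are flagged in ``traces``.
        Percent values are used exactly as printed (not re-closed).
        """
        basis = Basis(basis)
        if period not in ("before", "after"):
            raise ValueError("period must be 'before' or 'after'")
        col = {
            (True, Basis.PERCENT): "before_pct",
            (True, Basis.MG_PER_G_DW): "before_mg",
            (False, Basis.PERCENT): "after_pct",
            (False, Basis.MG_PER_G_DW): "after_mg",
        }.get((period == "before", basis))
        if col is None:
            raise ValueError(f"no pasture data on basis {basis.value}")
        series = self.fa[col]
        values = {label: (0.0 if pd.isna(v) else float(v)) for label, v in series.items()}
        traces = frozenset(label for label, v in series.items() if pd.isna(v))
        return FAProfile(
            sample_id=f"pasture_{period}_mean",
            basis=basis,
            values=values,
            tissue="plant",
            traces=traces,
        )


def load_pasture_mowing() -> PastureMowingTable:
    """Load the packaged pasture-grass before/after-mowing table."""
    with resources.files("nutrifa.data").joinpath("pasture_mowing.csv").open() as fh:
        raw = pd.read_csv(fh, na_values=["trace"], keep_default_na=True)
    fa = raw[raw.row_type == "fa"].set_index("fa_label").drop(columns="row_type")
    printed = raw[raw.row_type != "fa"].set_index("fa_label").drop(columns="row_type")
    return PastureMowingTable(fa=fa, printed=printed)
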