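"""Relative expression from qPCR threshold cycles by the 2^-ddCt method.

For a target gene and an internal reference (16S rRNA by default),
dCt = mean Ct(target) - mean Ct(reference) within each condition, then
ddCt = dCt(treated) - dCt(control) and the fold change is 2^-ddCt.
Replicate scatter is propagated as the root-sum-square of the standard
errors of the four Ct means.  A fold change above 2 or below 0.5 (strict
inequalities) is called significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import pandas as pd

REQUIRED_COLUMNS = ("sample_id", "condition", "gene", "replicate", "ct")
DEFAULT_REFERENCE = "16S"


class CtTableError(ValueError):
    """Missing genes/conditions or malformed Ct data."""


@dataclass(frozen=True)
class FoldChange:
    gene: str
    delta_delta_ct: float
    fold: float
    sd_delta_delta_ct: float
    significant: bool

    @property
    def fold_interval(self) -> tuple[float, float]:
        """Fold range one propagated SD either side of the estimate."""
        return (
            2 ** -(self.delta_delta_ct + self.sd_delta_delta_ct),
            2 ** -(self.delta_delta_ct - self.sd_delta_delta_ct),
        )


def load_ct_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    return validate_ct_table(df)


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise CtTableError(f"Ct table missing columns {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise CtTableError("Ct values must be positive cycles")
    bad = set(df["condition"].unique()) - {"treated", "control"}
    if bad:
        raise CtTableError(f"unknown conditions {sorted(bad)}")
    return df


def significance_call(fold: float, up: float = 2.0, down: float = 0.5) -> bool:
    """Fold-change significance rule: strict > up or strict < down."""
    if fold <= 0:
        raise ValueError("fold change must be positive")
    return fold > up or fold < down


def delta_delta_ct(
    table: pd.DataFrame,
    target: str,
    reference: str = DEFAULT_REFERENCE,
    up: float = 2.0,
    down: float = 0.5,
) -> FoldChange:
    """2^-ddCt relative expression of ``target`` against ``reference``.

    Replicate Ct values are averaged within each (condition, gene) cell
    before differencing.  The propagated SD combines the standard errors of
    the four cell means.
    """
    if target == reference:
        raise ValueError("target and reference genes must differ")
    table = validate_ct_table(table)

    def cell(condition: str, gene: str) -> pd.Series:
        sel = table[(table["condition"] == condition) & (table["gene"] == gene)]
        if sel.empty:
            raise CtTableError(f"no Ct rows for gene {gene!r} in {condition!r}")
        return sel["ct"]

    means, sems = {}, {}
    for cond in ("treated", "control"):
        for gene in (target, reference):
            ct = cell(cond, gene)
            means[(cond, gene)] = float(ct.mean())
            n = len(ct)
            sems[(cond, gene)] = float(ct.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0

    dct_treated = means[("treated", target)] - means[("treated", reference)]
    dct_control = means[("control", target)] - means[("control", reference)]
    ddct = dct_treated - dct_control
    sd = math.sqrt(sum(s**2 for s in sems.values()))
    fold = 2.0**-ddct
    return FoldChange(
        gene=target,
        delta_delta_ct=ddct,
        fold=fold,
        sd_delta_delta_ct=sd,
        significant=significance_call(fold, up=up, down=down),
    )


def fold_change_report(
    table: pd.DataFrame,
    targets: list[str] | None = None,
    reference: str = DEFAULT_REFERENCE,
    up: float = 2.0,
    down: float = 0.5,
) -> pd.DataFrame:
    """Fold changes for every (or the given) non-reference gene, as a frame."""
    table = validate_ct_table(table)
    if targets is None:
        targets = sorted(g for g in table["gene"].unique() if g != reference)
    rows = []
    for gene in targets:
        fc = delta_delta_ct(table, gene, reference=reference, up=up, down=down)
        rows.append(
            {
                "gene": gene,
                "delta_delta_ct": fc.delta_delta_ct,
                "fold": fc.fold,
                "sd_delta_delta_ct": fc.sd_delta_delta_ct,
                "significant": fc.significant,
            }
        )
    return pd.DataFrame(rows, columns=[
        "gene", "delta_delta_ct", "fold", "sd_delta_delta_ct", "significant"
    ])
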