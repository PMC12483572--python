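"""Reading long-format kin-term tables and writing tidy result tables.

Input tables are delimited UTF-8 text with one row per language x kin type x
form, in the style of large cross-linguistic kinship databases. A *dialect*
mapping declares which columns hold the language id, the kin-type code and
the form (plus optional glottocode/family columns), so differently-named
exports can be read without code changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .kinspace import G0, G1, KinTypeInventory, KinshipSystem, normalize_form

__all__ = [
    "TableDialect",
    "read_language_tables",
    "filter_analysable",
    "write_results",
    "entropy_table",
    "permutation_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TableDialect:
    """Column mapping and policies for a long-format term table."""

    language_col: str = "language_id"
    kin_type_col: str = "kin_type_code"
    form_col: str = "form"
    metadata_cols: tuple[str, ...] = ("glottocode", "family")
    sep: str = ","
    #: policy when a (language, kin type) lists multiple forms:
    #: "first" keeps the first row in file order, "error" raises.
    synonym_policy: str = "first"


def read_language_tables(
    path: str | Path,
    inventory: KinTypeInventory,
    dialect: TableDialect | None = None,
) -> list[KinshipSystem]:
    """Read a long-format term table into one KinshipSystem per language.

    Rows whose kin-type code is outside the inventory are ignored with a
    logged warning; rows whose form is empty after normalization are dropped
    the same way. Reading applies no analysability filter — that is a
    separate, explicit step (:func:`filter_analysable`).
    """
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"empty term table: {path}")
    required = {dialect.language_col, dialect.kin_type_col, dialect.form_col}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"term table {path} lacks required columns {sorted(missing)}")

    known = set(inventory.codes)
    unknown_codes = sorted(set(df[dialect.kin_type_col]) - known)
    if unknown_codes:
        logger.warning(
            "%s: ignoring %d rows with kin-type codes outside the inventory: %s",
            path, int(df[dialect.kin_type_col].isin(unknown_codes).sum()), unknown_codes,
        )
        df = df[df[dialect.kin_type_col].isin(known)]

    systems: list[KinshipSystem] = []
    for lang_id, group in df.groupby(dialect.language_col, sort=True):
        assignment: dict[str, str] = {}
        for _, row in group.iterrows():
            code = row[dialect.kin_type_col]
            form = normalize_form(row[dialect.form_col])
            if not form:
                logger.warning("%s: empty form for (%s, %s); dropped", path, lang_id, code)
                continue
            if code in assignment:
                if dialect.synonym_policy == "first":
                    continue
                raise ValueError(
                    f"{path}: multiple forms for ({lang_id}, {code}) under policy 'error'"
                )
            assignment[code] = form
        metadata = {
            col: group.iloc[0][col]
            for col in dialect.metadata_cols
            if col in group.columns and group.iloc[0][col]
        }
        systems.append(KinshipSystem(str(lang_id), assignment, metadata))
    return systems


def filter_analysable(
    systems: list[KinshipSystem], inventory: KinTypeInventory
) -> tuple[list[KinshipSystem], list[KinshipSystem]]:
    """Split systems into (kept, dropped) by the one-term-per-generation filter.

    A system is analysable when it assigns at least one term to a G+1 kin
    type and at least one to a G0 kin type; only those enter the entropy and
    compositionality analyses.
    """
    kept, dropped = [], []
    for system in systems:
        if system.assigned_codes(inventory, G1) and system.assigned_codes(inventory, G0):
            kept.append(system)
        else:
            dropped.append(system)
    return kept, dropped


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

ENTROPY_COLUMNS = [
    "system_id", "h_child_given_parent", "h_parent_given_child", "h_sym", "n_pairs",
]
PERMUTATION_COLUMNS = [
    "system_id", "observed", "baseline_mean", "baseline_sd", "z",
    "classification", "n_permutations", "seed",
]


def entropy_table(results: dict[str, "EntropyResult"]) -> pd.DataFrame:  # noqa: F821
    rows = [
        {
            "system_id": sid,
            "h_child_given_parent": r.h_child_given_parent,
            "h_parent_given_child": r.h_parent_given_child,
            "h_sym": r.h_sym,
            "n_pairs": r.n_pairs,
        }
        for sid, r in results.items()
    ]
    return pd.DataFrame(rows, columns=ENTROPY_COLUMNS)


def permutation_table(results: dict[str, "PermutationResult"]) -> pd.DataFrame:  # noqa: F821
    rows = [
        {
            "system_id": sid,
            "observed": r.observed,
            "baseline_mean": r.baseline_mean,
            "baseline_sd": r.baseline_sd,
            "z": r.z,
            "classification": r.classification,
            "n_permutations": r.n_permutations,
            "seed": r.seed,
        }
        for sid, r in results.items()
    ]
    return pd.DataFrame(rows, columns=PERMUTATION_COLUMNS)


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy result table as UTF-8 CSV with stable column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, encoding="utf-8")
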