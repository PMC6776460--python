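"""Registry file I/O.

Registries travel as plain CSV (RFC-4180 quoting via pandas) with one header
row, integer day dates, and the fixed, versioned column set
:data:`deltameld.simulate.REGISTRY_COLUMNS`.
"""

from __future__ import annotations

import pandas as pd

from .simulate import REGISTRY_COLUMNS

_DTYPES = {
    "registrant_id": str,
    "record_date": int,
    "meld_uncapped": int,
    "meld_capped": int,
    "serum_sodium": float,
    "status": str,
    "terminal_code": str,
    "age_years": float,
    "ethnicity": str,
    "diagnosis": str,
    "exception_case": int,
    "status_1": int,
}


def write_registry(df: pd.DataFrame, path) -> None:
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"registry frame missing columns: {missing}")
    extra = [c for c in df.columns if c not in REGISTRY_COLUMNS]
    df[REGISTRY_COLUMNS + extra].to_csv(path, index=False)


def read_registry(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={k: v for k, v in _DTYPES.items()})
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing registry columns: {missing}")
    return df
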