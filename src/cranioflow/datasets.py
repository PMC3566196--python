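"""Packaged per-subject study tables.

Two CSV fixtures reproduce the per-subject values printed in the study:
the drainage table (flows, jugular and secondary fractions, ordinal
venogram grade 1-6) and the hydrodynamic table (CSF stroke volume,
PTP-PG, ICVC, MRICP), for 15 mTBI subjects and 15 age/sex-matched
controls. Missing venogram grades are printed as ``n.a.`` and loaded as
NaN. A third fixture holds the printed group-summary rows so
recomputed summaries can be checked cell by cell. Fixture integrity is
guarded by SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import numpy as np
import pandas as pd

from .errors import IntegrityError

_CHECKSUMS = {
    "table1.csv": "0850d117062d5d9a5d6aa46d82e4691c595788cc86dbdcac6d9c6d7b6b7dfcbb",
    "table2.csv": "2d896755d82ceedf196f64f7ee9391125a3493e071ce72c646f730221bae0eba",
    "table_summaries.csv": "bf0bec3e8aa5d3f60d76eeaf32d19497c3af1db3e54218d7110835fac374bbd7",
}


def _read(name: str, verify: bool = True) -> pd.DataFrame:
    ref = resources.files("cranioflow.data").joinpath(name)
    raw = ref.read_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        expected = _CHECKSUMS[name]
        if expected != digest:
            raise IntegrityError(
                f"fixture {name} checksum mismatch: {digest} != {expected}")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), na_values=["n.a."])


def load_table1(verify: bool = True) -> pd.DataFrame:
    """Per-subject drainage table (flows, fractions, venogram grade)."""
    return _read("table1.csv", verify)


def load_table2(verify: bool = True) -> pd.DataFrame:
    """Per-subject hydrodynamic table (CSF SV, PTP-PG, ICVC, MRICP)."""
    return _read("table2.csv", verify)


def load_subject_table(verify: bool = True) -> pd.DataFrame:
    """Both tables merged into one record per subject."""
    t1 = load_table1(verify)
    t2 = load_table2(verify).drop(columns=["group", "pair_id", "age", "sex"])
    merged = t1.merge(t2, on="subject_id", validate="one_to_one")
    if len(merged) != len(t1):
        raise IntegrityError("table1/table2 subject ids do not match")
    return merged


def load_printed_summaries(verify: bool = True) -> pd.DataFrame:
    """The printed group-summary cells of both tables."""
    df = _read("table_summaries.csv", verify)
    df["printed"] = df["printed"].astype(float)
    return df
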