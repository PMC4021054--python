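"""Bundled reference data: the ten-knee cadaveric BV/TV validation table.

Ten paired measurements — microCT BV/TV and MR apparent BV/TV, in percent —
from the medial tibial plateau of both knees of five donors, keyed by donor
id and side.  This table is the published ground against which the
statistics pipeline is checked: the pooled Spearman correlation of the ten
pairs is 0.83 with a Fisher-z 95% CI of (0.42, 0.96).

Donor demographics ship alongside for completeness; no statistic here uses
them.
"""

from __future__ import annotations

import hashlib
import logging
from importlib import resources

import pandas as pd

from .agreement import PairedMeasurements

__all__ = [
    "load_cadaveric_bvtv",
    "load_cadaveric_demographics",
    "EXPECTED_POOLED_RHO_2DP",
]

logger = logging.getLogger(__name__)

#: Published pooled Spearman correlation of the bundled table, 2 decimals.
EXPECTED_POOLED_RHO_2DP = 0.83

_BVTV_SHA256 = "62ce8ab52d298b959af054fb7cc34936b3c1648ef67c0a398c55327c5c055aaf"
_DEMOGRAPHICS_SHA256 = "484c0f7b01b4bb2417cd80d57b604aa0c0e09b70d4c2a6102e7496aaec17cf51"


def _read_checked(name: str, expected_sha256: str) -> pd.DataFrame:
    ref = resources.files("trabmorph.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected_sha256:
        logger.warning(
            "bundled fixture %s has digest %s, expected %s — file may have been altered",
            name, digest, expected_sha256,
        )
    with ref.open("r") as fh:
        return pd.read_csv(fh)


def load_cadaveric_bvtv(as_paired: bool = True) -> PairedMeasurements | pd.DataFrame:
    """The ten paired (microCT, MR) BV/TV percents, one row per knee.

    Returns a :class:`~trabmorph.agreement.PairedMeasurements` by default,
    or the raw DataFrame with ``as_paired=False``.  A checksum mismatch is
    logged as a warning, not raised.
    """
    df = _read_checked("cadaveric_bvtv.csv", _BVTV_SHA256)
    return PairedMeasurements(df) if as_paired else df


def load_cadaveric_demographics() -> pd.DataFrame:
    """Donor demographics (age, sex, height, weight) for the five donors."""
    return _read_checked("cadaveric_demographics.csv", _DEMOGRAPHICS_SHA256)
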