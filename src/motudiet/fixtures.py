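"""Packaged worked-example dataset.

The package ships the per-taxon consumer-count matrix from the
two-predator bat diet study as a TSV fixture: one row per identified
prey taxon (order, family, species, identification confidence level)
and one occurrence-count column per predator — the number of
individual bats of each species whose feces contained the taxon.  The
fixture is checksum-verified on load so it cannot drift silently.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .diet import UtilizationMatrix

TABLE1_SHA256 = "24550175e927e0b973501ad7f44768e6ffec4c420bbdfc778030018836bdf56d"

PREDATOR_COLUMNS = ("P. austriacus", "P. auritus")


def _fixture_bytes() -> bytes:
    return (resources.files("motudiet") / "data" / "table1.tsv").read_bytes()


def load_table1_fixture() -> UtilizationMatrix:
    """Load the packaged prey-occurrence matrix.

    Resource labels are the species names, prefixed with the family for
    the per-family "Unknown" rows so every label is unique.  Order,
    family and confidence-level annotations ride along on the matrix.
    """
    raw = _fixture_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE1_SHA256:
        raise RuntimeError(
            f"fixture checksum mismatch: expected {TABLE1_SHA256}, got {digest}"
        )
    import io

    df = pd.read_csv(io.BytesIO(raw), sep="\t")
    labels = [
        f"{fam} {sp}" if sp == "Unknown" else sp
        for fam, sp in zip(df["family"], df["species"])
    ]
    df.index = pd.Index(labels, name="resource")
    counts = df[list(PREDATOR_COLUMNS)]
    annotations = df[["order", "family", "species", "confidence"]]
    return UtilizationMatrix(counts, annotations)
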