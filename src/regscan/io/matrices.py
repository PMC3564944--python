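"""Weight-matrix catalog readers (JASPAR raw PFM and TRANSFAC records).

Parsing is delegated to :mod:`Bio.motifs`; counts are kept unnormalised and
wrapped into :class:`~regscan.pwm.WeightMatrix` with the caller's
pseudocount.  Several matrices may model the same TF; :func:`group_by_tf`
reconstructs that grouping.
"""

from __future__ import annotations

from typing import IO

import numpy as np
from Bio import motifs as bio_motifs

from ..errors import FormatError
from ..pwm import BASES, WeightMatrix


def _counts_array(motif) -> np.ndarray:
    cols = [motif.counts[b] for b in BASES]
    arr = np.array(cols, dtype=float).T  # L x 4
    if (arr < 0).any():
        raise FormatError(f"negative counts in matrix {motif.name or '?'}")
    return arr


def read_pwm_catalog(stream: IO[str], dialect: str = "JASPAR_PFM",
                     pseudocount: float = 1.0) -> list[WeightMatrix]:
    """Read a matrix catalog.

    ``JASPAR_PFM``: ``>ID name`` headers with four labelled A/C/G/T rows.
    ``TRANSFAC``: ``//``-delimited records with ``P0`` headers and numbered
    position rows; integer and real counts both accepted.
    """
    out: list[WeightMatrix] = []
    if dialect == "JASPAR_PFM":
        try:
            parsed = bio_motifs.parse(stream, "jaspar")
        except Exception as e:
            raise FormatError(f"bad JASPAR PFM catalog: {e}") from e
        for m in parsed:
            out.append(WeightMatrix(
                id=m.matrix_id or m.name, tf_name=m.name or m.matrix_id,
                source="JASPAR", counts=_counts_array(m),
                pseudocount=pseudocount))
    elif dialect == "TRANSFAC":
        try:
            parsed = bio_motifs.parse(stream, "transfac", strict=False)
        except Exception as e:
            raise FormatError(f"bad TRANSFAC catalog: {e}") from e
        for m in parsed:
            mid = m.get("AC") or m.get("ID") or m.name
            name = m.get("ID") or m.get("NA") or mid
            out.append(WeightMatrix(
                id=mid, tf_name=name, source="TRANSFAC",
                counts=_counts_array(m), pseudocount=pseudocount))
    else:
        raise FormatError(f"unknown matrix dialect {dialect!r}")
    return out


def group_by_tf(catalog: list[WeightMatrix]) -> dict[str, list[WeightMatrix]]:
    """Group matrices by TF name (a TF may own several matrices)."""
    groups: dict[str, list[WeightMatrix]] = {}
    for m in catalog:
        groups.setdefault(m.tf_name, []).append(m)
    return groups


def write_jaspar(catalog: list[WeightMatrix], stream: IO[str]) -> None:
    """Write matrices in the JASPAR raw-PFM dialect."""
    for m in catalog:
        stream.write(f">{m.id} {m.tf_name}\n")
        for j, base in enumerate(BASES):
            row = " ".join(f"{int(v) if float(v).is_integer() else v:>6}"
                           for v in m.counts[:, j])
            stream.write(f"{base}  [{row} ]\n")
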