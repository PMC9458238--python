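"""Peptide-library annotation of spectral components.

Component m/z positions (GMM means) are matched against the measured
masses of tryptic peptides identified by LC-MS/MS, within a relative mass
tolerance (default +-0.05%).  The relative error is taken against the
library peptide mass, which is the reference measurement; matches are not
unique — a component may match several peptides, or none.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .preprocess import ComponentModel

__all__ = [
    "PeptideLibrary",
    "match_components",
    "proteins_for_components",
    "DEFAULT_TOLERANCE",
]

#: Relative mass tolerance of +-0.05%.
DEFAULT_TOLERANCE = 5e-4

LIBRARY_COLUMNS = ("mass", "sequence", "accession", "protein_name")


@dataclass
class PeptideLibrary:
    """LC-MS/MS peptide identifications: measured singly-protonated mass
    (Da), sequence, protein accession and name.

    The TSV schema is the four columns of :data:`LIBRARY_COLUMNS`; a
    converter from Mascot/PRIDE exports should produce exactly these
    columns (mass as the observed m/z of the [M+H]+ species).
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in LIBRARY_COLUMNS[:3] if c not in self.entries.columns]
        if missing:
            raise ValueError(f"library is missing columns {missing}")
        if "protein_name" not in self.entries.columns:
            self.entries = self.entries.assign(protein_name="")
        if len(self.entries) and (
            self.entries["accession"].astype(str).str.len().eq(0).any()
        ):
            raise ValueError("accessions must be nonempty")
        self.entries = (
            self.entries.sort_values("mass", kind="stable").reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path) -> "PeptideLibrary":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


def match_components(
    model: ComponentModel,
    library: PeptideLibrary,
    tol: float = DEFAULT_TOLERANCE,
) -> pd.DataFrame:
    """Match component means to library peptide masses within ``tol``.

    A component with mean ``mu`` matches a peptide of mass ``m`` when
    ``|mu - m| / m <= tol``.  The library is mass-sorted, so candidates
    are located by binary search.  Returns one row per (component,
    peptide) match, sorted by relative error within each component.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if len(library) == 0:
        warnings.warn("empty peptide library; no annotations possible")
        return pd.DataFrame(
            columns=["component_id", "mass", "sequence", "accession",
                     "protein_name", "relative_error"]
        )
    masses = library.entries["mass"].to_numpy(dtype=float)
    rows = []
    for k, mu in enumerate(model.means):
        # |mu - m| <= tol * m  <=>  mu / (1 + tol) <= m  and  m >= mu / ...
        lo = np.searchsorted(masses, mu / (1.0 + tol), side="left")
        hi = np.searchsorted(masses, mu / (1.0 - tol), side="right")
        for idx in range(lo, hi):
            err = abs(mu - masses[idx]) / masses[idx]
            if err <= tol:
                entry = library.entries.iloc[idx]
                rows.append(
                    {
                        "component_id": k,
                        "mass": float(masses[idx]),
                        "sequence": entry["sequence"],
                        "accession": entry["accession"],
                        "protein_name": entry.get("protein_name", ""),
                        "relative_error": float(err),
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=["component_id", "mass", "sequence", "accession",
                 "protein_name", "relative_error"],
    )
    return table.sort_values(
        ["component_id", "relative_error"], kind="stable"
    ).reset_index(drop=True)


def proteins_for_components(table: pd.DataFrame, components) -> list[str]:
    """Deduplicated protein accessions matched by a set of components."""
    components = set(int(c) for c in components)
    if table.empty or not components:
        return []
    hit = table[table["component_id"].isin(components)]
    seen: list[str] = []
    for acc in hit["accession"]:
        if acc not in seen:
            seen.append(acc)
    return seen
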