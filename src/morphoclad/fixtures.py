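"""Packaged Aphrodini leafhopper dataset.

The package ships the full published morphological matrix for the tribe
Aphrodini (23 taxa x 39 unordered characters: all 16 recognized
*Planaphrodes* species, six other Aphrodini outgroups, and the xestocephaline
root outgroup *Xestocephalus asper*), together with a documented
taxon-by-area coding of each species' range over four Palearctic regions:

    A  Europe
    B  Middle East and Western Asia
    C  Central Asia (including western China)
    D  Eastern Asia (including central and eastern China, Korea and Japan)

The area coding is reconstructed from the species' published distributions
(see ``docs/methods.md`` for the rules applied, e.g. how records from Russia
are assigned) and can be overridden with a user YAML mapping
``taxon -> area string``.
"""

from __future__ import annotations

import importlib.resources as _resources

import numpy as np
import yaml

from .io import read_matrix
from .matrix import AreaMatrix, CharacterMatrix

ROOT_OUTGROUP = "Xestocephalus asper"
AREA_CODES = ["A", "B", "C", "D"]


def _data_text(name: str) -> str:
    return (_resources.files("morphoclad") / "data" / name).read_text()


def load_aphrodini_matrix() -> CharacterMatrix:
    """The published 23-taxon x 39-character Aphrodini matrix."""
    return read_matrix(_data_text("aphrodini_matrix.tsv"), format="table")


def load_taxon_roles() -> dict[str, str]:
    """Taxon -> role, one of ``ingroup`` (the 16 *Planaphrodes* species),
    ``outgroup`` (other Aphrodini) or ``root_outgroup`` (*Xestocephalus*)."""
    roles = {}
    lines = _data_text("aphrodini_taxa.tsv").splitlines()
    for ln in lines[1:]:
        taxon, role, _areas = ln.split("\t")
        roles[taxon] = role
    return roles


def load_area_matrix(
    include_root_outgroup: bool = False,
    overrides: dict[str, str] | str | None = None,
) -> AreaMatrix:
    """Taxon-by-area presences for the Aphrodini dataset.

    Parameters
    ----------
    include_root_outgroup:
        *Xestocephalus* carries no range coding and is excluded from
        biogeographic analysis by default; requesting it raises an error
        unless an override provides its areas.
    overrides:
        Mapping (or path to a YAML file with a mapping) ``taxon -> areas``,
        e.g. ``{"Planaphrodes vallicola": "B"}``, replacing the packaged
        default coding for those taxa.
    """
    if isinstance(overrides, str):
        with open(overrides) as fh:
            overrides = yaml.safe_load(fh) or {}
    overrides = dict(overrides or {})
    taxa, rows = [], []
    for ln in _data_text("aphrodini_taxa.tsv").splitlines()[1:]:
        taxon, role, areas = ln.split("\t")
        areas = overrides.pop(taxon, areas)
        if role == "root_outgroup" and not include_root_outgroup:
            continue
        if not areas:
            raise ValueError(f"no area coding available for {taxon!r}")
        for a in areas:
            if a not in AREA_CODES:
                raise ValueError(f"unknown area code {a!r} for {taxon!r}")
        taxa.append(taxon)
        rows.append([1 if a in areas else 0 for a in AREA_CODES])
    if overrides:
        raise ValueError(f"area overrides for unknown taxa: {sorted(overrides)}")
    return AreaMatrix(taxa, list(AREA_CODES), np.array(rows, dtype=np.uint8))


def load_aphrodini_dataset(
    overrides: dict[str, str] | str | None = None,
) -> tuple[CharacterMatrix, AreaMatrix, dict[str, str]]:
    """Convenience loader: (character matrix, area matrix, taxon roles)."""
    return load_aphrodini_matrix(), load_area_matrix(overrides=overrides), load_taxon_roles()
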