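"""Gene sets for per-cell aggregate metrics.

Ships mitochondrial gene sets for human and mouse in gene-symbol, Ensembl
and Entrez identifier formats as plain-text resources (one identifier per
line). Matching against an experiment's gene universe is exact string
match after stripping Ensembl version suffixes (``ENSG00000198888.2`` ->
``ENSG00000198888``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import ParameterError

_ID_TYPES = ("symbol", "ensembl", "entrez")
_SPECIES = ("human", "mouse")

_ENSEMBL_VERSION = re.compile(r"\.\d+$")


@dataclass(frozen=True)
class GeneSet:
    """A named list of gene identifiers of one identifier type."""

    name: str
    ids: tuple[str, ...]
    id_type: str = "symbol"

    def __post_init__(self) -> None:
        if not self.ids:
            raise ParameterError(f"gene set '{self.name}' is empty")
        if len(set(self.ids)) != len(self.ids):
            raise ParameterError(f"gene set '{self.name}' has duplicate ids")
        if self.id_type not in _ID_TYPES:
            raise ParameterError(
                f"id_type must be one of {_ID_TYPES}, got '{self.id_type}'"
            )

    def match_mask(self, gene_ids: list[str]) -> np.ndarray:
        """Boolean mask of experiment genes belonging to this set.

        Both sides are compared after removing Ensembl version suffixes so
        versioned references (Gencode) still match.
        """
        wanted = {_ENSEMBL_VERSION.sub("", g) for g in self.ids}
        return np.array(
            [_ENSEMBL_VERSION.sub("", g) in wanted for g in gene_ids], dtype=bool
        )


def load_mito_geneset(species: str = "human", id_type: str = "symbol") -> GeneSet:
    """Load a shipped mitochondrial gene set."""
    if species not in _SPECIES:
        raise ParameterError(f"species must be one of {_SPECIES}")
    if id_type not in _ID_TYPES:
        raise ParameterError(f"id_type must be one of {_ID_TYPES}")
    fname = f"{species}_mito_{id_type}.txt"
    text = resources.files("scqc.resources").joinpath(fname).read_text()
    ids = tuple(line.strip() for line in text.splitlines() if line.strip())
    return GeneSet(name="mito", ids=ids, id_type=id_type)


def load_geneset_file(path: str | Path, name: str | None = None,
                      id_type: str = "symbol") -> GeneSet:
    """Load a user gene set from a one-identifier-per-line text file."""
    lines = Path(path).read_text().splitlines()
    ids = tuple(dict.fromkeys(line.strip() for line in lines if line.strip()))
    return GeneSet(name=name or Path(path).stem, ids=ids, id_type=id_type)


def resolve_mito_token(token: str) -> GeneSet:
    """Parse a ``<species>-<idtype>`` token (e.g. ``human-symbol``).

    Anything containing a path separator or an existing file is loaded as a
    custom gene-set file instead.
    """
    if Path(token).exists() or "/" in token:
        return load_geneset_file(token, name="mito")
    parts = token.split("-")
    if len(parts) != 2:
        raise ParameterError(
            f"mito gene-set token '{token}' is neither '<species>-<idtype>' "
            "nor an existing file"
        )
    return load_mito_geneset(species=parts[0], id_type=parts[1])
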