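"""Parameter and seed provenance for reproducible QC runs.

Every QC operation appends exactly one entry describing what ran, with which
parameters and which seed, so an exported run can be audited and replayed.
A single pipeline-level seed fans out to per-operation seeds through a
stable hash of the operation name; adding or removing one operation
therefore does not perturb the seeds of the others.
"""

from __future__ import annotations

import copy
import datetime
import hashlib
from dataclasses import dataclass, field
from typing import Any

__version__ = "0.1.0"

#: Upper bound for derived seeds; keeps them valid for every RNG API.
_SEED_MODULUS = 2**31


def derive_seed(global_seed: int, operation: str) -> int:
    """Derive a deterministic per-operation seed from a pipeline seed.

    Uses SHA-256 of ``"<seed>:<operation>"`` reduced mod 2^31, so the mapping
    is stable across platforms and Python versions (unlike ``hash()``).
    """
    digest = hashlib.sha256(f"{global_seed}:{operation}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % _SEED_MODULUS


@dataclass
class ProvenanceEntry:
    operation: str
    parameters: dict[str, Any]
    seed: int | None
    timestamp: str
    version: str

    def to_dict(self) -> dict[str, Any]:
        return {
            "operation": self.operation,
            "parameters": self.parameters,
            "seed": self.seed,
            "timestamp": self.timestamp,
            "version": self.version,
        }


@dataclass
class ProvenanceLog:
    """Ordered record of QC operations applied to an experiment."""

    entries: list[ProvenanceEntry] = field(default_factory=list)

    def record(
        self,
        operation: str,
        parameters: dict[str, Any] | None = None,
        seed: int | None = None,
    ) -> ProvenanceEntry:
        entry = ProvenanceEntry(
            operation=operation,
            parameters=dict(parameters or {}),
            seed=seed,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
            version=__version__,
        )
        self.entries.append(entry)
        return entry

    def copy(self) -> "ProvenanceLog":
        return ProvenanceLog(entries=copy.deepcopy(self.entries))

    def to_list(self) -> list[dict[str, Any]]:
        return [e.to_dict() for e in self.entries]

    @classmethod
    def from_list(cls, items: list[dict[str, Any]]) -> "ProvenanceLog":
        log = cls()
        for item in items:
            log.entries.append(
                ProvenanceEntry(
                    operation=item["operation"],
                    parameters=dict(item.get("parameters", {})),
                    seed=item.get("seed"),
                    timestamp=item.get("timestamp", ""),
                    version=item.get("version", ""),
                )
            )
        return log

    def __len__(self) -> int:
        return len(self.entries)
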