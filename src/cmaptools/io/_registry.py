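"""Format registry: every dialect registers a spec with read/write callables."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, List, Tuple


class FormatError(ValueError):
    """Malformed input for a registered format; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None) -> None:
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class FormatSpec:
    """Descriptor for one registered file dialect.

    ``lossy_fields`` names the Contact/Sequence fields the dialect cannot
    carry; every contact dialect round-trips at least
    (res1_index, res2_index) and, unless listed lossy, raw_score.
    """

    name: str
    kind: str  # "contact" | "sequence"
    columns: Tuple[str, ...]
    lossy_fields: FrozenSet[str]
    reader: Callable
    writer: Callable
    description: str = ""
    #: constant the reader substitutes when the dialect has no score column
    lossy_score_value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("contact", "sequence"):
            raise ValueError(f"unknown format kind {self.kind!r}")
        if self.name != self.name.lower():
            raise ValueError("format names are lowercase tokens")


class FormatRegistry:
    """Name -> FormatSpec mapping with kind-filtered views."""

    def __init__(self) -> None:
        self._specs: Dict[str, FormatSpec] = {}

    def register(self, spec: FormatSpec) -> None:
        if spec.name in self._specs:
            raise ValueError(f"format {spec.name!r} already registered")
        self._specs[spec.name] = spec

    def get(self, name: str) -> FormatSpec:
        try:
            return self._specs[name.lower()]
        except KeyError:
            raise KeyError(
                f"unknown format {name!r}; registered: {', '.join(sorted(self._specs))}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name.lower() in self._specs

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    def names(self, kind: str | None = None) -> List[str]:
        return sorted(
            s.name for s in self._specs.values() if kind is None or s.kind == kind
        )

    def contact_formats(self) -> List[str]:
        return self.names("contact")

    def sequence_formats(self) -> List[str]:
        return self.names("sequence")


#: The process-wide registry all dialects register into on import.
registry = FormatRegistry()
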