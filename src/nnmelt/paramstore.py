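"""XML thermodynamic-parameter store.

Parameter sets are XML files with a ``data`` root whose children each hold
an ``enthalpy`` and an ``entropy`` child (cal/mol and cal/(mol.K) — the
non-SI calorie convention of the nearest-neighbor literature).  Allowed
child elements and their attributes:

========== ==========================================
element    attributes
========== ==========================================
neighbor   sequence
initiation type
terminal   type
symmetry   (none)
mismatch   sequence, size, type, loop, closing
asymmetry  (none)
penalty    type
parameters sequence
bulge      size, sequence, type
closure    type
modified   sequence, type, sens
CNG        sequence, repeats
dangling   sequence, sens
========== ==========================================

``sequence`` values use the standard nearest-neighbor notation
``TOP/BOTTOM`` with the top strand 5'->3' and the bottom 3'->5', e.g.
``AA/TT``.  The ``data`` root carries ``type`` (hybridization scope) plus
optional bookkeeping attributes ``id``, ``initiation-rule``,
``reference-sodium`` (mol/L, default 1.0) and ``citation``.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

from .errors import MissingParameterError, ParameterLoadError

ELEMENT_ATTRIBUTES: dict[str, frozenset[str]] = {
    "neighbor": frozenset({"sequence"}),
    "initiation": frozenset({"type"}),
    "terminal": frozenset({"type"}),
    "symmetry": frozenset(),
    "mismatch": frozenset({"sequence", "size", "type", "loop", "closing"}),
    "asymmetry": frozenset(),
    "penalty": frozenset({"type"}),
    "parameters": frozenset({"sequence"}),
    "bulge": frozenset({"size", "sequence", "type"}),
    "closure": frozenset({"type"}),
    "modified": frozenset({"sequence", "type", "sens"}),
    "CNG": frozenset({"sequence", "repeats"}),
    "dangling": frozenset({"sequence", "sens"}),
}

_DATA_ATTRIBUTES = frozenset({"type", "id", "initiation-rule",
                              "reference-sodium", "citation"})


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


@dataclass(frozen=True)
class ThermoResult:
    """An (enthalpy, entropy) pair in cal/mol and cal/(mol.K)."""

    dh: float = 0.0
    ds: float = 0.0

    def __post_init__(self):
        if not (_finite(self.dh) and _finite(self.ds)):
            raise ValueError("enthalpy and entropy must be finite")

    def __add__(self, other: "ThermoResult") -> "ThermoResult":
        return ThermoResult(self.dh + other.dh, self.ds + other.ds)

    def scaled(self, factor: float) -> "ThermoResult":
        return ThermoResult(self.dh * factor, self.ds * factor)


ZERO = ThermoResult(0.0, 0.0)


@dataclass(frozen=True)
class DescriptorKey:
    """Typed key of one parameter entry: element kind + its attributes."""

    element_kind: str
    attributes: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self):
        if self.element_kind not in ELEMENT_ATTRIBUTES:
            raise ParameterLoadError(
                f"unknown parameter element {self.element_kind!r}")
        allowed = ELEMENT_ATTRIBUTES[self.element_kind]
        for name, _ in self.attributes:
            if name not in allowed:
                raise ParameterLoadError(
                    f"attribute {name!r} is not allowed on element "
                    f"{self.element_kind!r}")

    def get(self, name: str) -> str | None:
        for k, v in self.attributes:
            if k == name:
                return v
        return None

    def __str__(self) -> str:
        attrs = " ".join(f'{k}="{v}"' for k, v in sorted(self.attributes))
        return f"<{self.element_kind} {attrs}>" if attrs else f"<{self.element_kind}>"


def key(element_kind: str, **attributes: str) -> DescriptorKey:
    """Convenience constructor: ``key('neighbor', sequence='AA/TT')``."""
    return DescriptorKey(element_kind,
                         frozenset((k, str(v)) for k, v in attributes.items()))


def _reverse_sequence(seq: str) -> str | None:
    # AB/CD read from the other end of the duplex is DC/BA.  Multi-character
    # symbols (A*, Al, X_C ...) are respected by tokenizing lazily.
    if "/" not in seq:
        return None
    top, _, bottom = seq.partition("/")
    from .sequences import tokenize  # local import: avoid cycle at load
    try:
        rtop = "".join(reversed(tokenize(bottom).symbols()))
        rbottom = "".join(reversed(tokenize(top).symbols()))
    except Exception:
        return None
    return f"{rtop}/{rbottom}"


def reversed_key(k: DescriptorKey) -> DescriptorKey | None:
    """The reverse-orientation equivalent of a sequence-keyed entry."""
    seq = k.get("sequence")
    if seq is None:
        return None
    rseq = _reverse_sequence(seq)
    if rseq is None or rseq == seq:
        return None
    attrs = {name: v for name, v in k.attributes}
    attrs["sequence"] = rseq
    return key(k.element_kind, **attrs)


@dataclass
class ParameterSet:
    """One loaded thermodynamic dataset."""

    id: str
    hybridization_scope: str
    entries: dict[DescriptorKey, ThermoResult] = field(default_factory=dict)
    metadata: dict[str, str | float] = field(default_factory=dict)

    @property
    def reference_sodium(self) -> float:
        return float(self.metadata.get("reference-sodium", 1.0))

    @property
    def initiation_rule(self) -> str:
        return str(self.metadata.get("initiation-rule", "per_terminal"))

    def __contains__(self, k: DescriptorKey) -> bool:
        try:
            self.lookup(k)
            return True
        except MissingParameterError:
            return False

    def lookup(self, k: DescriptorKey) -> ThermoResult:
        """Exact-match lookup with reverse-orientation fallback.

        For sequence-keyed entries, if the literal orientation is absent the
        entry stored under both strands reversed is returned when present.
        """
        hit = self.entries.get(k)
        if hit is not None:
            return hit
        rk = reversed_key(k)
        if rk is not None:
            hit = self.entries.get(rk)
            if hit is not None:
                return hit
        raise MissingParameterError(k, self.id)

    def lookup_optional(self, k: DescriptorKey) -> ThermoResult | None:
        try:
            return self.lookup(k)
        except MissingParameterError:
            return None


def lookup(pset: ParameterSet, k: DescriptorKey) -> ThermoResult:
    """Module-level alias of :meth:`ParameterSet.lookup`."""
    return pset.lookup(k)


def _parse_energy(elem: ET.Element, child: str, where: str) -> float:
    node = elem.find(child)
    if node is None or node.text is None:
        raise ParameterLoadError(f"element {where} lacks a {child!r} child")
    try:
        return float(node.text.strip())
    except ValueError:
        raise ParameterLoadError(
            f"non-numeric {child} text {node.text!r} in element {where}") from None


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Read one XML parameter file into a :class:`ParameterSet`."""
    path = Path(path)
    try:
        tree = ET.parse(path)
    except (ET.ParseError, OSError) as exc:
        raise ParameterLoadError(f"cannot read parameter file {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "data":
        raise ParameterLoadError(
            f"{path}: root element must be 'data', found {root.tag!r}")
    for name in root.attrib:
        if name not in _DATA_ATTRIBUTES:
            raise ParameterLoadError(f"{path}: unknown 'data' attribute {name!r}")
    if "type" not in root.attrib:
        raise ParameterLoadError(f"{path}: 'data' element lacks the 'type' attribute")

    metadata: dict[str, str | float] = {
        k: v for k, v in root.attrib.items() if k not in ("type", "id")}
    if "reference-sodium" in metadata:
        try:
            metadata["reference-sodium"] = float(metadata["reference-sodium"])
        except ValueError:
            raise ParameterLoadError(
                f"{path}: non-numeric reference-sodium attribute") from None

    pset = ParameterSet(
        id=root.attrib.get("id", path.stem),
        hybridization_scope=root.attrib["type"],
        metadata=metadata,
    )
    for elem in root:
        if elem.tag not in ELEMENT_ATTRIBUTES:
            raise ParameterLoadError(f"{path}: unknown element {elem.tag!r}")
        try:
            k = key(elem.tag, **elem.attrib)
        except ParameterLoadError as exc:
            raise ParameterLoadError(f"{path}: {exc}") from None
        where = str(k)
        dh = _parse_energy(elem, "enthalpy", where)
        ds = _parse_energy(elem, "entropy", where)
        if k in pset.entries:
            raise ParameterLoadError(f"{path}: duplicate entry {where}")
        pset.entries[k] = ThermoResult(dh, ds)
    return pset


def write_parameter_set(pset: ParameterSet, path: str | Path) -> Path:
    """Serialize a set so that :func:`load_parameter_set` round-trips it."""
    path = Path(path)
    root = ET.Element("data", {"type": pset.hybridization_scope, "id": pset.id})
    for name, value in sorted(pset.metadata.items()):
        root.set(name, repr(value) if isinstance(value, float) else str(value))
    for k, thermo in pset.entries.items():
        elem = ET.SubElement(root, k.element_kind,
                             {name: v for name, v in sorted(k.attributes)})
        ET.SubElement(elem, "enthalpy").text = repr(thermo.dh)
        ET.SubElement(elem, "entropy").text = repr(thermo.ds)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)
    return path


class ParameterRegistry:
    """Directory-based registry mapping dataset ids to XML files.

    Files are discovered lazily; ``extra_dirs`` (e.g. from the CLI ``--data``
    option) take precedence over the packaged payload.
    """

    def __init__(self, directories: list[Path]):
        self.directories = [Path(d) for d in directories]
        self._cache: dict[str, ParameterSet] = {}

    def path_for(self, set_id: str) -> Path:
        for d in self.directories:
            candidate = d / f"{set_id}.xml"
            if candidate.exists():
                return candidate
        raise ParameterLoadError(
            f"no parameter file {set_id}.xml under "
            f"{', '.join(str(d) for d in self.directories)}")

    def get(self, set_id: str) -> ParameterSet:
        if set_id not in self._cache:
            self._cache[set_id] = load_parameter_set(self.path_for(set_id))
        return self._cache[set_id]

    def available(self) -> list[str]:
        ids: set[str] = set()
        for d in self.directories:
            if d.is_dir():
                ids.update(p.stem for p in d.glob("*.xml"))
        return sorted(ids)


def default_registry(extra_dir: str | Path | None = None) -> ParameterRegistry:
    dirs: list[Path] = []
    if extra_dir is not None:
        dirs.append(Path(extra_dir))
    dirs.append(Path(__file__).parent / "data")
    return ParameterRegistry(dirs)
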