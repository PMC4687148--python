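"""Version-pinned reference data: datasets, release manifests, provenance.

Reference data (identifier mappings, ortholog tables, ontology releases,
annotation corpora ...) change between releases of their upstream sources.
To make a pipeline run reproducible, every data file is stored under a
calendar date stamp and every release carries a manifest pinning each tool
to one (dataset, version).  Resolving a tool under a release then always
yields the same file, and a rerun under the same manifest reads the same
bytes.  Users may override any pin with their own file; overrides are
recorded in a provenance log, never applied silently.

On disk a registry is a human-diffable directory::

    <root>/datasets.yaml                  index of registered files
    <root>/data/<name>/<version>/<file>   the data files themselves
    <root>/releases/<id>/manifest         YAML tool -> [name, version]
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import shutil
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Optional

import yaml

from .exceptions import (
    ChecksumMismatchError,
    DuplicateDatasetError,
    ToolNotPinnedError,
    UnknownReleaseError,
)


def file_digest(path: Path | str) -> str:
    """Hex SHA-256 of a file's content."""
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass(frozen=True)
class DatasetDescriptor:
    """One time-stamped data file.

    ``version`` is an ISO-8601 date; ``path`` is relative to the registry
    root; ``checksum`` is the hex SHA-256 of the file content.
    """

    name: str
    version: str
    path: str
    checksum: str
    source: str = ""
    build: Optional[str] = None

    def __post_init__(self) -> None:
        _dt.date.fromisoformat(self.version)  # raises ValueError if malformed


@dataclass
class ProvenanceEntry:
    tool: str
    release_id: Optional[str]
    descriptor: DatasetDescriptor
    overridden: bool


class Registry:
    """A rooted collection of dataset descriptors plus release manifests."""

    def __init__(self, root: Path | str):
        self.root = Path(root)
        self._datasets: dict[tuple[str, str], DatasetDescriptor] = {}
        # release_id -> {tool -> (name, version)}
        self._manifests: dict[str, dict[str, tuple[str, str]]] = {}
        self.provenance: list[ProvenanceEntry] = []

    # -- registration -------------------------------------------------

    def register(self, descriptor: DatasetDescriptor) -> DatasetDescriptor:
        """Register a descriptor; idempotent for identical checksums.

        The file must exist under the registry root and its digest must
        match the descriptor (a descriptor with an empty checksum has the
        digest filled in).  Re-registering a (name, version) with a
        different checksum is a conflict.
        """
        full = self.root / descriptor.path
        if not full.is_file():
            raise FileNotFoundError(f"dataset file missing: {full}")
        digest = file_digest(full)
        if descriptor.checksum and descriptor.checksum != digest:
            raise ChecksumMismatchError(
                f"{descriptor.name} {descriptor.version}: stored digest does "
                f"not match file content"
            )
        descriptor = DatasetDescriptor(
            descriptor.name, descriptor.version, descriptor.path, digest,
            descriptor.source, descriptor.build,
        )
        key = (descriptor.name, descriptor.version)
        existing = self._datasets.get(key)
        if existing is not None:
            if existing.checksum != descriptor.checksum:
                raise DuplicateDatasetError(
                    f"{key} already registered with a different checksum"
                )
            return existing
        self._datasets[key] = descriptor
        return descriptor

    def add_file(
        self,
        name: str,
        version: str,
        source_path: Path | str,
        source: str = "",
        build: Optional[str] = None,
    ) -> DatasetDescriptor:
        """Copy a file into ``data/<name>/<version>/`` and register it."""
        source_path = Path(source_path)
        rel = Path("data") / name / version / source_path.name
        dest = self.root / rel
        dest.parent.mkdir(parents=True, exist_ok=True)
        if dest.resolve() != source_path.resolve():
            shutil.copyfile(source_path, dest)
        return self.register(
            DatasetDescriptor(name, version, str(rel), "", source, build)
        )

    # -- lookup -------------------------------------------------------

    def get(self, name: str, version: str) -> DatasetDescriptor:
        try:
            return self._datasets[(name, version)]
        except KeyError:
            raise KeyError(f"no dataset {name!r} version {version!r}") from None

    def list_versions(self, name: str) -> list[str]:
        """All registered versions of a dataset, ascending by date."""
        versions = [v for (n, v) in self._datasets if n == name]
        return sorted(versions, key=_dt.date.fromisoformat)

    def datasets(self) -> Iterable[DatasetDescriptor]:
        return list(self._datasets.values())

    # -- manifests ----------------------------------------------------

    def pin(self, release_id: str | int, tool: str, name: str, version: str) -> None:
        """Pin a tool to a dataset version within a release manifest."""
        if (name, version) not in self._datasets:
            raise KeyError(f"cannot pin unregistered dataset {(name, version)}")
        manifest = self._manifests.setdefault(str(release_id), {})
        if tool in manifest and manifest[tool] != (name, version):
            raise DuplicateDatasetError(
                f"tool {tool!r} already pinned in release {release_id}"
            )
        manifest[tool] = (name, version)

    def manifest(self, release_id: str | int) -> dict[str, tuple[str, str]]:
        try:
            return dict(self._manifests[str(release_id)])
        except KeyError:
            raise UnknownReleaseError(f"no manifest for release {release_id}") from None

    def releases(self) -> list[str]:
        return sorted(self._manifests)

    def resolve(
        self,
        tool: str,
        release_id: str | int | None = None,
        override: Optional[DatasetDescriptor] = None,
    ) -> DatasetDescriptor:
        """Return the descriptor pinned for (tool, release).

        An ``override`` descriptor is returned verbatim and the
        substitution is recorded in the provenance log.
        """
        if override is not None:
            self.provenance.append(
                ProvenanceEntry(tool, None if release_id is None else str(release_id),
                                override, overridden=True)
            )
            return override
        if release_id is None:
            raise UnknownReleaseError("no release given and no override supplied")
        manifest = self.manifest(release_id)
        if tool not in manifest:
            raise ToolNotPinnedError(
                f"tool {tool!r} not pinned in release {release_id}"
            )
        descriptor = self._datasets[manifest[tool]]
        self.provenance.append(
            ProvenanceEntry(tool, str(release_id), descriptor, overridden=False)
        )
        return descriptor

    def resolve_path(self, tool: str, release_id=None, override=None) -> Path:
        descriptor = self.resolve(tool, release_id, override)
        return self.root / descriptor.path

    # -- integrity ----------------------------------------------------

    def verify(self, descriptor: DatasetDescriptor) -> str:
        """Recompute the digest of the descriptor's file: 'ok' | 'mismatch'."""
        full = self.root / descriptor.path
        if not full.is_file():
            raise FileNotFoundError(f"dataset file missing: {full}")
        return "ok" if file_digest(full) == descriptor.checksum else "mismatch"

    def verify_all(self) -> dict[tuple[str, str], str]:
        return {
            key: self.verify(desc) for key, desc in sorted(self._datasets.items())
        }

    # -- serialization ------------------------------------------------

    def save(self) -> None:
        """Write datasets.yaml and one manifest file per release."""
        self.root.mkdir(parents=True, exist_ok=True)
        index = [asdict(d) for _, d in sorted(self._datasets.items())]
        with open(self.root / "datasets.yaml", "w", encoding="utf-8") as handle:
            yaml.safe_dump(index, handle, sort_keys=False)
        for release_id, manifest in self._manifests.items():
            rel_dir = self.root / "releases" / release_id
            rel_dir.mkdir(parents=True, exist_ok=True)
            payload = {tool: list(pin) for tool, pin in sorted(manifest.items())}
            with open(rel_dir / "manifest", "w", encoding="utf-8") as handle:
                yaml.safe_dump(payload, handle, sort_keys=True)

    @classmethod
    def open(cls, root: Path | str) -> "Registry":
        registry = cls(root)
        index_path = registry.root / "datasets.yaml"
        if index_path.is_file():
            with open(index_path, "r", encoding="utf-8") as handle:
                for record in yaml.safe_load(handle) or []:
                    registry.register(DatasetDescriptor(**record))
        releases_dir = registry.root / "releases"
        if releases_dir.is_dir():
            for rel_dir in sorted(releases_dir.iterdir()):
                manifest_path = rel_dir / "manifest"
                if not manifest_path.is_file():
                    continue
                with open(manifest_path, "r", encoding="utf-8") as handle:
                    payload = yaml.safe_load(handle) or {}
                for tool, (name, version) in payload.items():
                    registry.pin(rel_dir.name, tool, name, version)
        return registry


__all__ = ["DatasetDescriptor", "ProvenanceEntry", "Registry", "file_digest"]
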