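"""Study manifest: the roster tying animals, group labels and data
files together, plus validation.

A manifest is a YAML file::

    seed: 17
    animals:
      - id: sham_saline_00
        lesion: sham            # sham | 6-OHDA
        treatment: saline       # saline | LD24 | R2.5 | LD24+R2.5
        open_field: of/sham_saline_00.csv
        checking: cc/sham_saline_00.csv
        epm: epm/sham_saline_00.csv
        states: states/sham_saline_00.csv
        trials: rigt/sham_saline_00.csv   # optional (lesioned cohort)
    sections:
      cells: sections/cells.csv
      outlines: sections/outlines.json

Paths are relative to the manifest's directory.  Validation checks that
every referenced file exists and parses, that group labels come from
the eight design cells, and that no animal id repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

LESIONS = ("sham", "6-OHDA")
TREATMENTS = ("saline", "LD24", "R2.5", "LD24+R2.5")
ASSAY_KEYS = ("open_field", "checking", "epm", "states", "trials")


class ManifestError(ValueError):
    pass


@dataclass
class AnimalEntry:
    id: str
    lesion: str
    treatment: str
    files: dict[str, Path] = field(default_factory=dict)

    @property
    def group(self) -> str:
        return f"{self.lesion}:{self.treatment}"


@dataclass
class StudyManifest:
    seed: int
    animals: list[AnimalEntry]
    sections: dict[str, Path]
    root: Path
    warnings: list[str] = field(default_factory=list)

    def by_group(self) -> dict[str, list[AnimalEntry]]:
        out: dict[str, list[AnimalEntry]] = {}
        for a in self.animals:
            out.setdefault(a.group, []).append(a)
        return out


def validate_manifest(path, parse_files: bool = True) -> StudyManifest:
    """Load and cross-check a manifest; raises :class:`ManifestError`
    with a descriptive message on the first structural problem."""
    path = Path(path)
    root = path.parent
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - yaml details vary
        raise ManifestError(f"{path}: not valid YAML ({exc})") from exc
    if not isinstance(doc, dict) or "animals" not in doc:
        raise ManifestError(f"{path}: manifest must define 'animals'")
    seen = set()
    animals = []
    warnings: list[str] = []
    for rec in doc["animals"]:
        aid = str(rec.get("id", ""))
        if not aid:
            raise ManifestError("animal entry without id")
        if aid in seen:
            raise ManifestError(f"duplicated animal id {aid!r}")
        seen.add(aid)
        lesion, treatment = rec.get("lesion"), rec.get("treatment")
        if lesion not in LESIONS:
            raise ManifestError(f"animal {aid}: unknown lesion label {lesion!r}")
        if treatment not in TREATMENTS:
            raise ManifestError(f"animal {aid}: unknown treatment label {treatment!r}")
        files = {}
        for key in ASSAY_KEYS:
            if key in rec and rec[key]:
                fp = root / rec[key]
                if not fp.exists():
                    raise ManifestError(f"animal {aid}: missing {key} file {fp}")
                files[key] = fp
        if not files:
            warnings.append(f"animal {aid} has no data files")
        animals.append(AnimalEntry(aid, lesion, treatment, files))
    sections = {}
    if "sections" in doc and doc["sections"]:
        for key in ("cells", "outlines"):
            if key not in doc["sections"]:
                raise ManifestError(f"sections block must name a {key} file")
            fp = root / doc["sections"][key]
            if not fp.exists():
                raise ManifestError(f"missing sections {key} file {fp}")
            sections[key] = fp
    manifest = StudyManifest(
        int(doc.get("seed", 0)), animals, sections, root, warnings
    )
    if parse_files:
        _parse_all(manifest)
    return manifest


def _parse_all(manifest: StudyManifest) -> None:
    from . import io as _io

    readers = {
        "open_field": _io.read_trajectory_csv,
        "checking": _io.read_trajectory_csv,
        "epm": _io.read_trajectory_csv,
        "states": _io.read_event_log_csv,
        "trials": _io.read_trials_csv,
    }
    for a in manifest.animals:
        for key, fp in a.files.items():
            try:
                readers[key](fp)
            except Exception as exc:
                raise ManifestError(f"animal {a.id}: {key} file {fp}: {exc}") from exc
    if manifest.sections:
        try:
            _io.read_sections(manifest.sections["cells"], manifest.sections["outlines"])
        except Exception as exc:
            raise ManifestError(f"sections files: {exc}") from exc
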