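"""Stimulus manifests, participant tokens, and result persistence.

A stimulus set is a directory of mono WAV files plus a CSV manifest with
the header ``filename,difficulty_level,response_options,correct_answer,
condition`` (columns beyond ``filename`` optional per task type; response
options are '|'-delimited). Results are written as a versioned JSON
document (lossless round-trip, settings embedded for provenance) plus a
flat per-trial CSV for analysis software. Participant tokens are opaque
128-bit identifiers carrying no personal data.
"""

from __future__ import annotations

import dataclasses
import json
import zipfile
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import read_wav
from .errors import ManifestError, SchemaVersionError

__all__ = [
    "RESULTS_SCHEMA_VERSION",
    "MANIFEST_COLUMNS",
    "ManifestRow",
    "StimulusManifest",
    "TrialRecord",
    "ParticipantToken",
    "load_manifest",
    "generate_token",
    "export_results",
    "import_results",
    "export_trials_csv",
    "pack_stimulus_bundle",
    "unpack_stimulus_bundle",
]

RESULTS_SCHEMA_VERSION = 1
MANIFEST_COLUMNS = ["filename", "difficulty_level", "response_options", "correct_answer", "condition"]
OPTION_DELIMITER = "|"


@dataclass(frozen=True)
class ManifestRow:
    filename: str
    difficulty_level: float | None = None
    response_options: tuple[str, ...] | None = None
    correct_answer: str | None = None
    condition: str | None = None


@dataclass(frozen=True)
class StimulusManifest:
    """Validated stimulus table; rows keep manifest order."""

    rows: tuple[ManifestRow, ...]
    base_dir: Path | None = None

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def levels(self) -> list[float]:
        """Distinct difficulty levels, ascending."""
        return sorted({r.difficulty_level for r in self.rows if r.difficulty_level is not None})

    def by_level(self, level: float, atol: float = 1e-9) -> list[ManifestRow]:
        return [
            r
            for r in self.rows
            if r.difficulty_level is not None and abs(r.difficulty_level - level) <= atol
        ]


def _parse_row(idx: int, row: pd.Series) -> ManifestRow:
    """idx is the spreadsheet row number (header = row 1)."""

    def cell(name):
        v = row.get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
            return None
        return str(v).strip()

    filename = cell("filename")
    if not filename:
        raise ManifestError(f"row {idx}: missing filename")
    level_raw = cell("difficulty_level")
    level = None
    if level_raw is not None:
        try:
            level = float(level_raw)
        except ValueError:
            raise ManifestError(f"row {idx}: difficulty_level {level_raw!r} is not numeric") from None
    options_raw = cell("response_options")
    options = tuple(o.strip() for o in options_raw.split(OPTION_DELIMITER)) if options_raw else None
    answer = cell("correct_answer")
    if answer is not None and options is not None and answer not in options:
        raise ManifestError(
            f"row {idx}: correct_answer {answer!r} not among response_options {list(options)}"
        )
    return ManifestRow(filename, level, options, answer, cell("condition"))


def load_manifest(
    path: str | Path,
    *,
    require_difficulty: bool = False,
    require_closed_set: bool = False,
    check_audio: bool = True,
) -> StimulusManifest:
    """Load and validate a stimulus manifest (CSV; XLSX read-only).

    Every failure is reported with its spreadsheet row number (header =
    row 1). ``require_difficulty`` enforces a difficulty level on every
    row (adaptive tasks); ``require_closed_set`` enforces response
    options + correct answer. With ``check_audio`` each referenced file
    must exist and be a readable mono WAV, relative to the manifest's
    directory.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        frame = pd.read_excel(path, dtype=str)
    else:
        frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if "filename" not in frame.columns:
        raise ManifestError(f"row 1: manifest header must include 'filename'; got {list(frame.columns)}")

    rows: list[ManifestRow] = []
    seen: dict[str, int] = {}
    for i, (_, raw) in enumerate(frame.iterrows()):
        idx = i + 2  # data starts on spreadsheet row 2
        row = _parse_row(idx, raw)
        if row.filename in seen:
            raise ManifestError(
                f"row {idx}: duplicate filename {row.filename!r} (first seen on row {seen[row.filename]})"
            )
        seen[row.filename] = idx
        if require_difficulty and row.difficulty_level is None:
            raise ManifestError(f"row {idx}: adaptive task requires difficulty_level")
        if require_closed_set and (row.response_options is None or row.correct_answer is None):
            raise ManifestError(
                f"row {idx}: closed-set task requires response_options and correct_answer"
            )
        if check_audio:
            wav_path = path.parent / row.filename
            if not wav_path.exists():
                raise ManifestError(f"row {idx}: audio file not found: {wav_path}")
            try:
                read_wav(wav_path)
            except Exception as exc:
                raise ManifestError(f"row {idx}: unreadable audio {wav_path}: {exc}") from exc
        rows.append(row)
    return StimulusManifest(tuple(rows), base_dir=path.parent)


@dataclass(frozen=True)
class TrialRecord:
    """One presented stimulus and its response — the atom of result export."""

    stimulus_id: str
    response: object = None
    correct: bool | None = None
    response_time_ms: float = 0.0
    timestamp: str = ""
    condition: str | None = None
    level: float | None = None
    run: int = 0
    phase: str = ""
    practice: bool = False
    keyword_score: int | None = None

    def __post_init__(self) -> None:
        if self.response_time_ms < 0:
            raise ValueError(f"response_time_ms must be ≥ 0, got {self.response_time_ms}")


def utc_now_iso() -> str:
    return datetime.now(timezone.utc).isoformat()


@dataclass(frozen=True)
class ParticipantToken:
    """Opaque anonymous participant identifier, unique within a project."""

    token: str
    project_id: str
    created: str


def generate_token(project_id: str, rng: np.random.Generator, existing=()) -> ParticipantToken:
    """Generate a 128-bit anonymous token (collision chance < 2⁻⁶⁴ even
    across billions of draws); retries against ``existing`` within the
    project so tokens are unique per project by construction."""
    existing = set(existing)
    while True:
        token = "".join(f"{b:02x}" for b in rng.integers(0, 256, size=16, dtype=np.uint8))
        if token not in existing:
            return ParticipantToken(token=token, project_id=str(project_id), created=utc_now_iso())


# ---------------------------------------------------------------------------
# Results persistence

def export_results(records, settings: dict, path: str | Path) -> None:
    """Write a versioned JSON results document (records + settings)."""
    doc = {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "settings": settings,
        "trials": [dataclasses.asdict(r) for r in records],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def import_results(path: str | Path) -> tuple[list[TrialRecord], dict]:
    """Read a results document; exact inverse of :func:`export_results`.

    Raises :class:`SchemaVersionError` on any other schema version — an
    explicit migration point rather than a silent best-effort parse.
    """
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != RESULTS_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"results file {path} has schema_version {version!r}; "
            f"this engine reads version {RESULTS_SCHEMA_VERSION} (migrate the file first)"
        )
    records = [TrialRecord(**t) for t in doc["trials"]]
    return records, doc["settings"]


def export_trials_csv(records, path: str | Path) -> None:
    """Flat per-trial CSV for analysis software (one row per trial)."""
    columns = [
        "stimulus_id", "condition", "level", "response", "correct",
        "response_time_ms", "timestamp", "run", "phase", "practice", "keyword_score",
    ]
    frame = pd.DataFrame([dataclasses.asdict(r) for r in records])
    if frame.empty:
        frame = pd.DataFrame(columns=columns)
    else:
        frame["response"] = frame["response"].map(json.dumps)
        frame = frame[columns]
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Stimulus bundles

def pack_stimulus_bundle(files, bundle_path: str | Path, *, base_dir: str | Path | None = None) -> None:
    """Zip stimulus files (store paths relative to ``base_dir``)."""
    bundle_path = Path(bundle_path)
    with zipfile.ZipFile(bundle_path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for f in files:
            f = Path(f)
            arcname = str(f.relative_to(base_dir)) if base_dir is not None else f.name
            zf.write(f, arcname=arcname)


def unpack_stimulus_bundle(bundle_path: str | Path, out_dir: str | Path) -> list[Path]:
    """Unpack a bundle; contents are byte-identical to what was packed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with zipfile.ZipFile(bundle_path) as zf:
        zf.extractall(out_dir)
        return [out_dir / name for name in zf.namelist()]
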