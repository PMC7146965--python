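"""Reading and writing of external artifacts.

Handles the four on-disk formats:

* core template file — plain text, first line is a marker-bearing SMILES
  (``[*]`` / ``[n*]`` SM slots, ``[*sugar*]`` sugar slots);
* fragment files — one fragment per line, wrapped in ``[R]`` anchors;
* chunked library output — ``LIBRARIES/<timestamp>_mcrl_<k>.smiles`` files
  of at most ``chunk_size`` SMILES lines each;
* the run-information manifest recording every parameter of a run.
"""

from __future__ import annotations

import datetime as _dt
import re
import warnings
from pathlib import Path
from typing import Iterable, Iterator

import yaml

from .model import (
    ANCHOR,
    CoreTemplate,
    EnumerationConfig,
    Fragment,
    FragmentKind,
    FragmentLibrary,
    Slot,
    SlotKind,
)
from .stereo import classify_join_stereo

TIMESTAMP_FORMAT = "%Y-%m-%d-%H-%M-%S"

#: slot markers: unlabeled / digit-labelled SM slots and sugar slots
MARKER_RE = re.compile(r"\[(\d*)\*\]|\[\*sugar\*\]")

#: permissive shape of a legal SMILES bracket atom: optional isotope digits,
#: then an element symbol (or aromatic lowercase), then tags/charges/H-counts
_BRACKET_ATOM_RE = re.compile(r"\[\d{0,3}[A-Za-z][^\[\]]*\]")


class CoreTemplateError(ValueError):
    pass


class FragmentFileError(ValueError):
    pass


def parse_core_template(text: str) -> CoreTemplate:
    """Parse a marker-bearing core SMILES into segments and ordered slots.

    Whitespace anywhere in the string is stripped first: published core
    strings carry typographic spaces (``(= O)``) that are rendering
    artifacts, not chemistry.  Slot order is left-to-right textual order;
    digit labels on SM markers are recorded but carry no semantics.

    A core without any slot is legal (it enumerates to itself) but triggers
    a warning.
    """
    if not text or not text.strip():
        raise CoreTemplateError("core template text is empty")
    clean = "".join(text.split())

    depth = 0
    for i, ch in enumerate(clean):
        if ch == "[":
            if depth:
                raise CoreTemplateError(f"nested '[' at position {i}")
            depth += 1
        elif ch == "]":
            if not depth:
                raise CoreTemplateError(f"unmatched ']' at position {i}")
            depth -= 1
    if depth:
        raise CoreTemplateError("unbalanced brackets: missing ']'")

    for m in re.finditer(r"\[[^\]]*\]", clean):
        token = m.group(0)
        if MARKER_RE.fullmatch(token) or _BRACKET_ATOM_RE.fullmatch(token):
            continue
        raise CoreTemplateError(f"unrecognized bracket token {token!r}")

    slots: list[Slot] = []
    segments: list[str] = []
    last = 0
    for m in MARKER_RE.finditer(clean):
        segments.append(clean[last : m.start()])
        if m.group(0).endswith("sugar*]"):
            kind, label = SlotKind.SUGAR, None
        else:
            kind = SlotKind.SM
            label = int(m.group(1)) if m.group(1) else None
        slots.append(Slot(kind=kind, index=len(slots), label=label))
        last = m.end()
    segments.append(clean[last:])

    if not slots:
        warnings.warn("core template contains no substitution slots")
    return CoreTemplate(raw_text=clean, segments=segments, slots=slots)


def load_core_file(path: str | Path) -> CoreTemplate:
    """Load a core from a text file; only the first non-blank line is used."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise CoreTemplateError(f"core file {path} is empty")
    return parse_core_template(lines[0])


def load_fragment_library(
    path: str | Path, kind: FragmentKind | str
) -> FragmentLibrary:
    """Load an anchored fragment file: one ``[R]...[R]`` SMILES per line.

    Bodies are stored in file line order with anchors stripped; ids default
    to ``<kind><line#>`` (zero-padded), since the published input files are
    bare SMILES lines.  The joining-atom stereo status is classified at load
    time from the capped body.
    """
    kind = FragmentKind(kind)
    path = Path(path)
    fragments: list[Fragment] = []
    n_seen = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if not (line.startswith(ANCHOR) and line.endswith(ANCHOR)) or len(
            line
        ) < 2 * len(ANCHOR) + 1:
            raise FragmentFileError(
                f"{path} line {lineno}: fragment must start and end with "
                f"{ANCHOR!r}: {line!r}"
            )
        body = line[len(ANCHOR) : -len(ANCHOR)]
        if ANCHOR in body:
            raise FragmentFileError(
                f"{path} line {lineno}: more than two {ANCHOR!r} anchors"
            )
        n_seen += 1
        fragments.append(
            Fragment(
                id=f"{kind.value}{n_seen:03d}",
                kind=kind,
                body=body,
                join_stereo=classify_join_stereo(body),
            )
        )
    if not fragments:
        raise FragmentFileError(f"fragment file {path} has no fragments")
    return FragmentLibrary(fragments, kind=kind, source_path=str(path))


def _timestamp(now: _dt.datetime | None = None) -> str:
    return (now or _dt.datetime.now()).strftime(TIMESTAMP_FORMAT)


def write_library_chunks(
    records: Iterable[str],
    out_dir: str | Path,
    chunk_size: int = 1_000_000,
    timestamp: _dt.datetime | None = None,
) -> list[Path]:
    """Stream SMILES records into numbered ``.smiles`` chunk files.

    Files land under ``<out_dir>/LIBRARIES`` as
    ``<timestamp>_mcrl_<k>.smiles`` (k counting from 1), each holding at
    most ``chunk_size`` lines.  Passing an explicit ``timestamp`` makes two
    runs of the same stream byte- and name-identical.  Returns the paths in
    creation order; an empty stream creates no file.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    lib_dir = Path(out_dir) / "LIBRARIES"
    lib_dir.mkdir(parents=True, exist_ok=True)
    ts = _timestamp(timestamp)

    paths: list[Path] = []
    fh = None
    in_chunk = 0
    try:
        for smiles in records:
            if fh is None or in_chunk >= chunk_size:
                if fh is not None:
                    fh.close()
                path = lib_dir / f"{ts}_mcrl_{len(paths) + 1}.smiles"
                fh = path.open("w")
                paths.append(path)
                in_chunk = 0
            fh.write(smiles + "\n")
            in_chunk += 1
    finally:
        if fh is not None:
            fh.close()
    return paths


def iter_library_chunks(paths: Iterable[str | Path]) -> Iterator[str]:
    """Yield SMILES lines back from chunk files, in file then line order."""
    for path in paths:
        with Path(path).open() as fh:
            for line in fh:
                line = line.strip()
                if line:
                    yield line


def write_info_file(
    config: EnumerationConfig,
    out_dir: str | Path,
    timestamp: _dt.datetime | None = None,
) -> Path:
    """Write the human-readable run manifest ``<timestamp>_info.txt``.

    Records the core, the fragment file paths, all five user parameters,
    the seed and the timestamp as ``key: value`` YAML so the manifest
    round-trips mechanically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ts = _timestamp(timestamp)
    manifest = {
        "timestamp": ts,
        "core": config.core.raw_text,
        "sm_file": config.sm_library.source_path,
        "sugar_file": config.sugar_library.source_path,
        "max_sm_repeats": config.max_sm_repeats,
        "min_sugars": config.min_sugars,
        "library_size": config.library_size,
        "enumerate_sm_stereo": config.enumerate_sm_stereo,
        "enumerate_sugar_stereo": config.enumerate_sugar_stereo,
        "chunk_size": config.chunk_size,
        "plan_mode": config.plan_mode,
        "hydroxyl_body": config.hydroxyl_body,
        "seed": config.seed,
    }
    path = out / f"{ts}_info.txt"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def read_info_file(path: str | Path) -> dict:
    """Parse a run manifest back into a dict (inverse of write_info_file)."""
    return yaml.safe_load(Path(path).read_text())
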