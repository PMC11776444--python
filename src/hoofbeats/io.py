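"""Reading and writing footfall onset annotations.

Two on-disk forms are supported: Praat TextGrid point tiers (both the long
and the short text dialect, UTF-8 or UTF-16) and a flat CSV datasheet with
columns ``individual_id,gait,onset_s`` — the annotation-to-datasheet step
of the workflow. Onsets are absolute seconds from file start; each file or
CSV group is assumed to be a single-gait segment with transitions excised.
"""

from __future__ import annotations

import codecs
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, TierNotFoundError, ValidationError
from .recording import GAITS, FootfallRecording

__all__ = [
    "read_textgrid",
    "write_textgrid",
    "read_timeseries_csv",
    "write_timeseries_csv",
]

logger = logging.getLogger(__name__)

CSV_COLUMNS = ("individual_id", "gait", "onset_s")
#: Two annotations closer than this are treated as one double-clicked event.
DUPLICATE_TOLERANCE = 1e-9


# --------------------------------------------------------------------------
# TextGrid
# --------------------------------------------------------------------------

def _decode(raw: bytes) -> str:
    for bom, enc in (
        (codecs.BOM_UTF16_LE, "utf-16-le"),
        (codecs.BOM_UTF16_BE, "utf-16-be"),
        (codecs.BOM_UTF8, "utf-8-sig"),
    ):
        if raw.startswith(bom):
            return raw.decode(enc)
    try:
        return raw.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise FormatError(f"could not decode TextGrid text: {exc}") from exc


def _parse_long(lines: list[str]) -> dict[str, tuple[str, list[float]]]:
    """Return {tier name: (class, point times)} from a long-dialect TextGrid."""
    tiers: dict[str, tuple[str, list[float]]] = {}
    klass = None
    current: list[float] | None = None
    in_points = False
    for line in lines:
        m = re.match(r'class\s*=\s*"(.*)"', line)
        if m:
            klass = m.group(1)
            in_points = False
            continue
        m = re.match(r'name\s*=\s*"(.*)"', line)
        if m and klass is not None:
            current = []
            tiers[m.group(1)] = (klass, current)
            continue
        if re.match(r"points\s*(\[\d+\])?:?", line):
            in_points = True
            continue
        if re.match(r"intervals\s*(\[\d+\])?:?", line):
            in_points = False
            continue
        m = re.match(r"(?:number|time)\s*=\s*(\S+)", line)
        if m and in_points and current is not None and klass == "TextTier":
            current.append(float(m.group(1)))
    return tiers


def _parse_short(lines: list[str]) -> dict[str, tuple[str, list[float]]]:
    """Return {tier name: (class, point times)} from a short-dialect TextGrid."""
    body = [ln for ln in lines[2:] if ln]  # skip File type / Object class
    tiers: dict[str, tuple[str, list[float]]] = {}
    try:
        i = 2  # skip global xmin, xmax
        if not body[i].startswith("<"):
            raise FormatError("expected <exists> flag in short TextGrid")
        i += 1
        n_tiers = int(body[i]); i += 1
        for _ in range(n_tiers):
            klass = body[i].strip('"'); i += 1
            name = body[i].strip('"'); i += 1
            i += 2  # tier xmin, xmax
            n_items = int(body[i]); i += 1
            times: list[float] = []
            if klass == "TextTier":
                for _ in range(n_items):
                    times.append(float(body[i])); i += 2  # number, mark
            else:  # IntervalTier: xmin, xmax, text per item
                i += 3 * n_items
            tiers[name] = (klass, times)
    except (IndexError, ValueError) as exc:
        raise FormatError(f"malformed short-format TextGrid: {exc}") from exc
    return tiers


def _parse_textgrid(text: str) -> dict[str, tuple[str, list[float]]]:
    lines = [ln.strip() for ln in text.splitlines()]
    if not any("ooTextFile" in ln for ln in lines[:3]):
        raise FormatError("not a Praat ooTextFile")
    if not any("TextGrid" in ln for ln in lines[:4]):
        raise FormatError("not a TextGrid object")
    is_long = any(re.match(r"item\s*\[", ln) for ln in lines) or any(
        ln.startswith("xmin") for ln in lines
    )
    return _parse_long(lines) if is_long else _parse_short(lines)


def _infer_labels(path: Path, individual_id: str | None, gait: str | None):
    """Fill missing labels from a ``<individual>_<gait>`` file-stem pattern."""
    parts = path.stem.split("_")
    if individual_id is None:
        individual_id = parts[0]
    if gait is None:
        for part in parts[1:]:
            if part.lower() in GAITS:
                gait = part.lower()
                break
    if gait is None:
        raise ValidationError(
            f"gait label not given and not inferable from filename {path.name!r}"
        )
    return individual_id, gait


def read_textgrid(
    path,
    tier_name: str,
    individual_id: str | None = None,
    gait: str | None = None,
) -> FootfallRecording:
    """Read one point tier of a Praat TextGrid as a footfall recording.

    Both text dialects and UTF-8/UTF-16 encodings are handled. Point times
    are returned sorted ascending; events closer than 1 ns are collapsed
    (annotation double-clicks) with a logged warning. ``individual_id`` and
    ``gait``, if not given, are inferred from an ``<id>_<gait>`` file stem.
    """
    path = Path(path)
    tiers = _parse_textgrid(_decode(path.read_bytes()))
    if tier_name not in tiers:
        raise TierNotFoundError(
            f"tier {tier_name!r} not found in {path.name}; "
            f"available: {sorted(tiers)}"
        )
    klass, times = tiers[tier_name]
    if klass != "TextTier":
        raise TierNotFoundError(f"tier {tier_name!r} is a {klass}, not a point tier")
    times = np.sort(np.asarray(times, dtype=float))
    if times.size > 1:
        keep = np.concatenate([[True], np.diff(times) > DUPLICATE_TOLERANCE])
        if not keep.all():
            logger.warning(
                "%s: collapsed %d duplicate point(s) at %s",
                path.name, int((~keep).sum()), times[~keep][:5],
            )
            times = times[keep]
    individual_id, gait = _infer_labels(path, individual_id, gait)
    return FootfallRecording(individual_id=individual_id, gait=gait, onsets=times)


def write_textgrid(
    rec: FootfallRecording,
    path,
    tier_name: str = "footfalls",
    dialect: str = "long",
) -> Path:
    """Write a recording as a single-point-tier TextGrid (long or short)."""
    path = Path(path)
    xmax = float(rec.onsets[-1]) if rec.n_onsets else 1.0
    if dialect == "long":
        out = [
            'File type = "ooTextFile"',
            'Object class = "TextGrid"',
            "",
            "xmin = 0 ",
            f"xmax = {xmax:.6f} ",
            "tiers? <exists> ",
            "size = 1 ",
            "item []: ",
            "    item [1]:",
            '        class = "TextTier" ',
            f'        name = "{tier_name}" ',
            "        xmin = 0 ",
            f"        xmax = {xmax:.6f} ",
            f"        points: size = {rec.n_onsets} ",
        ]
        for i, t in enumerate(rec.onsets, start=1):
            out += [
                f"        points [{i}]:",
                f"            number = {t:.6f} ",
                '            mark = "" ',
            ]
    elif dialect == "short":
        out = [
            'File type = "ooTextFile"',
            'Object class = "TextGrid"',
            "",
            "0",
            f"{xmax:.6f}",
            "<exists>",
            "1",
            '"TextTier"',
            f'"{tier_name}"',
            "0",
            f"{xmax:.6f}",
            str(rec.n_onsets),
        ]
        for t in rec.onsets:
            out += [f"{t:.6f}", '""']
    else:
        raise ValidationError(f"unknown TextGrid dialect {dialect!r}")
    path.write_text("\n".join(out) + "\n", encoding="utf-8")
    return path


# --------------------------------------------------------------------------
# CSV datasheet
# --------------------------------------------------------------------------

def write_timeseries_csv(recordings: list[FootfallRecording], path) -> int:
    """Write recordings as a flat onset datasheet; returns data-row count."""
    if not recordings:
        raise ValidationError("recordings must be nonempty")
    frames = [
        pd.DataFrame(
            {
                "individual_id": rec.individual_id,
                "gait": rec.gait,
                "onset_s": rec.onsets,
            }
        )
        for rec in recordings
    ]
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.6f")
    return len(df)


def read_timeseries_csv(path) -> list[FootfallRecording]:
    """Read an onset datasheet back into recordings.

    Rows are grouped by (individual_id, gait) in order of first appearance;
    onsets are sorted within each group. Malformed or negative times raise
    a :class:`ValidationError` naming the offending line numbers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"individual_id": str, "gait": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path.name}: empty CSV") from exc
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {sorted(missing)}")
    onsets = pd.to_numeric(df["onset_s"], errors="coerce")
    bad = df.index[~np.isfinite(onsets)]
    if len(bad):
        # +2: one for the header row, one for 1-based numbering
        lines = [int(i) + 2 for i in bad[:10]]
        raise ValidationError(f"{path.name}: unparseable onset_s at line(s) {lines}")
    neg = df.index[onsets < 0]
    if len(neg):
        lines = [int(i) + 2 for i in neg[:10]]
        raise ValidationError(f"{path.name}: negative onset_s at line(s) {lines}")
    df["onset_s"] = onsets
    recordings = []
    for (ind, gait), grp in df.groupby(["individual_id", "gait"], sort=False):
        times = np.sort(grp["onset_s"].to_numpy())
        if times.size > 1:
            keep = np.concatenate([[True], np.diff(times) > DUPLICATE_TOLERANCE])
            if not keep.all():
                logger.warning(
                    "%s/%s: collapsed %d duplicate onset(s)",
                    ind, gait, int((~keep).sum()),
                )
                times = times[keep]
        recordings.append(
            FootfallRecording(individual_id=str(ind), gait=str(gait), onsets=times)
        )
    return recordings
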