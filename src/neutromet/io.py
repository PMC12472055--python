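"""Core containers and file formats.

Holds the in-memory types shared by the whole pipeline (:class:`Spectrum`,
:class:`BinDefinition`, :class:`PatternFile`, :class:`FeatureTable`) plus
readers/writers for the plain-text formats the pipeline touches:

* 1D spectra as JCAMP-DX (single-block, real 1D, ``##XYDATA=(X++(Y..Y))``
  with AFFN or SQZ/DIF/DUP encoded ordinates) or two-column tabular text;
* pattern files (bin boundaries with metabolite annotations) as comma- or
  tab-delimited text;
* feature tables (samples x bins) as tab-delimited text with embedded bin
  and state metadata.

Internal axis convention: chemical shift is stored strictly ascending.
NMR display convention (high ppm on the left) only matters at the file
boundary; writers may emit descending axes and readers re-sort.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, InvariantError
from .version import __version__

# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class Spectrum:
    """A single 1D NMR trace.

    Parameters
    ----------
    ppm:
        Chemical-shift axis in ppm, strictly ascending.
    intensity:
        Intensities in arbitrary units, same length as ``ppm``.
    frequency_mhz:
        Spectrometer 1H frequency in MHz (default 700, a cryoprobe system).
    meta:
        Free-form sample metadata (sample_id, group, cell_count, n_scans,
        isolation_method, provenance of corrections...).
    """

    ppm: np.ndarray
    intensity: np.ndarray
    frequency_mhz: float = 700.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise InvariantError("ppm and intensity must be 1-D arrays")
        if self.ppm.size != self.intensity.size or self.ppm.size < 2:
            raise InvariantError(
                "ppm and intensity must have equal length >= 2 "
                f"(got {self.ppm.size} and {self.intensity.size})"
            )
        d = np.diff(self.ppm)
        if np.any(d <= 0):
            raise InvariantError("ppm axis must be strictly ascending")
        if not self.frequency_mhz > 0:
            raise InvariantError("frequency_mhz must be positive")

    def copy(self) -> "Spectrum":
        return Spectrum(
            self.ppm.copy(), self.intensity.copy(), self.frequency_mhz, dict(self.meta)
        )

    def __len__(self) -> int:
        return int(self.ppm.size)


@dataclass(frozen=True)
class BinDefinition:
    """One spectral bin: a ppm interval around a peak multiplet.

    NMR convention: the *left* edge is the higher chemical shift, so
    ``left_ppm > right_ppm`` and the width is ``left_ppm - right_ppm``.
    """

    bin_id: str
    left_ppm: float
    right_ppm: float
    annotation: str = "unknown"
    metabolite_id: str = ""

    def __post_init__(self) -> None:
        if not self.left_ppm > self.right_ppm:
            raise InvariantError(
                f"bin {self.bin_id!r}: left_ppm ({self.left_ppm}) must exceed "
                f"right_ppm ({self.right_ppm})"
            )

    @property
    def width(self) -> float:
        return self.left_ppm - self.right_ppm

    @property
    def is_unknown(self) -> bool:
        return self.annotation.strip().lower() == "unknown"

    @property
    def group_key(self) -> str:
        """Grouping key for CRS: metabolite_id, falling back to annotation."""
        return self.metabolite_id or self.annotation


@dataclass
class PatternFile:
    """Ordered set of non-overlapping bin definitions.

    Bins are kept sorted by descending left boundary (reading order of an
    NMR spectrum). Overlapping bins are rejected outright: overlapping
    integrals double-count area and break the CRS interpretation.
    """

    bins: list

    def __post_init__(self) -> None:
        self.bins = sorted(self.bins, key=lambda b: -b.left_ppm)
        ids = [b.bin_id for b in self.bins]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InvariantError(f"duplicate bin_ids in pattern: {dup}")
        for a, b in zip(self.bins, self.bins[1:]):
            # sorted descending by left edge; b overlaps a iff b reaches past a's right edge
            if b.left_ppm > a.right_ppm + 1e-12:
                raise InvariantError(
                    f"overlapping bins: {a.bin_id!r} [{a.right_ppm}, {a.left_ppm}] "
                    f"and {b.bin_id!r} [{b.right_ppm}, {b.left_ppm}]"
                )

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self):
        return iter(self.bins)

    def metabolite_groups(self) -> dict:
        """Map group key -> list of candidate bins, annotated bins only."""
        groups: dict = {}
        for b in self.bins:
            if b.is_unknown:
                continue
            groups.setdefault(b.group_key, []).append(b)
        return groups

    @property
    def unknown_bins(self) -> list:
        return [b for b in self.bins if b.is_unknown]


VALID_STATES = ("raw", "normalised", "scaled")


@dataclass
class FeatureTable:
    """Samples x bins matrix of integrated areas with row/column metadata.

    ``state`` tracks the preprocessing stage: ``raw`` (non-negative areas),
    ``normalised`` (rows sum to 1 after total-area normalisation) or
    ``scaled`` (Pareto-scaled, column means zero).
    """

    values: np.ndarray
    sample_meta: pd.DataFrame
    bins: list
    state: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvariantError("values must be a 2-D matrix")
        n, p = self.values.shape
        if self.state not in VALID_STATES:
            raise InvariantError(f"state must be one of {VALID_STATES}")
        if not isinstance(self.sample_meta, pd.DataFrame):
            self.sample_meta = pd.DataFrame(self.sample_meta)
        if len(self.sample_meta) != n:
            raise InvariantError(
                f"sample_meta has {len(self.sample_meta)} rows for {n} samples"
            )
        if len(self.bins) != p:
            raise InvariantError(f"{len(self.bins)} bin definitions for {p} columns")
        if np.any(~np.isfinite(self.values)):
            raise InvariantError("feature table contains missing/non-finite values")
        if self.state == "raw" and np.any(self.values < 0):
            raise InvariantError("raw feature table contains negative values")
        self.sample_meta = self.sample_meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_ids(self) -> list:
        return [b.bin_id for b in self.bins]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.bin_ids)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(), self.sample_meta.copy(), list(self.bins), self.state
        )

    def select_bins(self, bin_ids: Sequence[str]) -> "FeatureTable":
        index = {b: i for i, b in enumerate(self.bin_ids)}
        cols = [index[b] for b in bin_ids]
        return FeatureTable(
            self.values[:, cols],
            self.sample_meta.copy(),
            [self.bins[i] for i in cols],
            self.state,
        )


# --------------------------------------------------------------------------
# spectra: tabular format
# --------------------------------------------------------------------------

_META_LINE = re.compile(r"^#\s*([A-Za-z_][\w.]*)\s*:\s*(.*?)\s*$")


def _coerce_scalar(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def _sorted_spectrum(ppm, intensity, frequency_mhz, meta) -> Spectrum:
    ppm = np.asarray(ppm, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    order = np.argsort(ppm)
    ppm, intensity = ppm[order], intensity[order]
    if np.any(np.diff(ppm) == 0):
        raise InvariantError("spectrum axis contains duplicated ppm values")
    return Spectrum(ppm, intensity, frequency_mhz, meta)


def _read_tabular_spectrum(path: Path) -> Spectrum:
    meta: dict = {}
    xs: list = []
    ys: list = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = _META_LINE.match(line)
            if m:
                meta[m.group(1)] = _coerce_scalar(m.group(2))
            continue
        parts = re.split(r"[,\s]+", line)
        if len(parts) < 2:
            raise FormatError(f"{path}: expected two columns, got line {raw!r}")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric data line {raw!r}") from exc
    if len(xs) < 2:
        raise FormatError(f"{path}: fewer than 2 data points")
    freq = float(meta.pop("frequency_mhz", 700.0))
    return _sorted_spectrum(xs, ys, freq, meta)


def write_tabular_spectrum(
    s: Spectrum, path, *, include_header: bool = True, timestamps: bool = True
) -> None:
    """Write a two-column (ppm, intensity) text spectrum."""
    path = Path(path)
    lines = []
    if include_header:
        lines.append("# neutromet spectrum v1")
        lines.append(f"# package_version: {__version__}")
        if timestamps:
            lines.append(f"# written: {datetime.datetime.now().isoformat()}")
        lines.append(f"# frequency_mhz: {s.frequency_mhz:.10g}")
        for key, value in s.meta.items():
            if isinstance(value, (str, int, float)):
                lines.append(f"# {key}: {value}")
    for x, y in zip(s.ppm, s.intensity):
        lines.append(f"{x:.12g}\t{y:.17g}")
    path.write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# spectra: JCAMP-DX subset (single-block, real 1D)
# --------------------------------------------------------------------------

# ASDF pseudo-digit tables (JCAMP-DX 4.24/5.00)
_SQZ = {"@": 0}
_SQZ.update({chr(ord("A") + i): i + 1 for i in range(9)})
_SQZ.update({chr(ord("a") + i): -(i + 1) for i in range(9)})
_DIF = {"%": 0}
_DIF.update({chr(ord("J") + i): i + 1 for i in range(9)})
_DIF.update({chr(ord("j") + i): -(i + 1) for i in range(9)})
_DUP = {chr(ord("S") + i): i + 1 for i in range(8)}
_DUP["s"] = 9

_NUM_START = re.compile(r"[+\-0-9.@A-Ia-i%J-Rj-rS-Zs]")


def _tokenise_asdf(text: str) -> list:
    """Split an XYDATA line body into (mode, value) tokens.

    mode is 'affn', 'sqz', 'dif' or 'dup'. Pseudo-digits replace the sign
    and leading digit of a value; remaining characters are ordinary digits.
    """
    tokens = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch in " \t,;":
            i += 1
            continue
        if ch in _SQZ or ch in _DIF or ch in _DUP:
            if ch in _SQZ:
                mode, lead = "sqz", _SQZ[ch]
            elif ch in _DIF:
                mode, lead = "dif", _DIF[ch]
            else:
                mode, lead = "dup", _DUP[ch]
            j = i + 1
            while j < n and text[j].isdigit():
                j += 1
            digits = text[i + 1 : j]
            value = float(f"{abs(lead)}{digits}" or "0")
            if lead < 0:
                value = -value
            tokens.append((mode, value))
            i = j
        elif ch in "+-0123456789.":
            j = i + 1
            while j < n and (text[j].isdigit() or text[j] in ".eE" or
                             (text[j] in "+-" and text[j - 1] in "eE")):
                j += 1
            tokens.append(("affn", float(text[i:j])))
            i = j
        else:
            raise FormatError(f"unexpected character {ch!r} in XYDATA line")
    return tokens


def _decode_xydata(lines: Iterable[str]) -> tuple:
    """Decode an (X++(Y..Y)) table; returns (x_starts, y_rows, dif_flags)."""
    x_starts, y_rows, dif_flags = [], [], []
    for line in lines:
        tokens = _tokenise_asdf(line)
        if not tokens:
            continue
        if tokens[0][0] not in ("affn", "sqz"):
            raise FormatError("XYDATA line does not start with an abscissa value")
        x_starts.append(tokens[0][1])
        ys: list = []
        used_dif = False
        last_was_dif = False
        k = 1
        while k < len(tokens):
            mode, value = tokens[k]
            if mode in ("affn", "sqz"):
                ys.append(value)
                last_was_dif = False
            elif mode == "dif":
                if not ys:
                    raise FormatError("DIF value with no preceding ordinate")
                ys.append(ys[-1] + value)
                used_dif = True
                last_was_dif = True
            elif mode == "dup":
                if k < 2:
                    raise FormatError("DUP with no preceding value")
                prev_mode, prev_value = tokens[k - 1]
                for _ in range(int(value) - 1):
                    if prev_mode == "dif":
                        ys.append(ys[-1] + prev_value)
                    else:
                        ys.append(ys[-1])
            k += 1
        y_rows.append(ys)
        dif_flags.append(used_dif and last_was_dif)
    return x_starts, y_rows, dif_flags


def _read_jcampdx_spectrum(path: Path) -> Spectrum:
    text = path.read_text()
    if "##TITLE" not in text:
        raise FormatError(f"{path}: not a JCAMP-DX file (no ##TITLE record)")
    if text.count("##TITLE") > 1:
        raise FormatError(
            f"{path}: compound/multi-block JCAMP-DX files are not supported; "
            "supply a single-block real 1D record"
        )
    # collect labelled data records
    records: dict = {}
    current_label = None
    data_lines: list = []
    for raw in text.splitlines():
        line = raw.split("$$")[0].rstrip()  # strip comments
        if not line:
            continue
        if line.startswith("##"):
            label, _, value = line[2:].partition("=")
            label = re.sub(r"[ \-_/]", "", label).upper()
            current_label = label
            if label == "XYDATA":
                if "(X++(Y..Y))" not in value.replace(" ", ""):
                    raise FormatError(
                        f"{path}: unsupported XYDATA variable list {value.strip()!r}"
                    )
                data_lines = []
            else:
                records[label] = value.strip()
        elif current_label == "XYDATA":
            data_lines.append(line)
    if "NTUPLES" in records:
        raise FormatError(f"{path}: NTUPLES records are not supported")
    if current_label != "XYDATA" and not data_lines:
        raise FormatError(f"{path}: no XYDATA table found")

    def fget(label, default=None):
        if label in records:
            return float(records[label])
        return default

    xfactor = fget("XFACTOR", 1.0)
    yfactor = fget("YFACTOR", 1.0)
    npoints = records.get("NPOINTS")
    x_starts, y_rows, dif_flags = _decode_xydata(data_lines)
    ys: list = []
    for i, row in enumerate(y_rows):
        if i > 0 and dif_flags[i - 1] and row:
            # first ordinate of a line following a DIF-ending line is a check value
            if ys and abs(row[0] - ys[-1]) > max(1e-6, 1e-6 * abs(ys[-1])):
                raise FormatError(f"{path}: DIF checkpoint mismatch at line {i}")
            row = row[1:] if ys else row
        ys.extend(row)
    y = np.asarray(ys, dtype=float) * yfactor
    if npoints is not None and int(float(npoints)) != y.size:
        raise FormatError(
            f"{path}: NPOINTS={npoints} but decoded {y.size} ordinates"
        )
    firstx = fget("FIRSTX", x_starts[0] * xfactor if x_starts else None)
    lastx = fget("LASTX")
    if firstx is None or lastx is None:
        raise FormatError(f"{path}: FIRSTX/LASTX required to build the axis")
    x = np.linspace(firstx, lastx, y.size)

    freq = fget("OBSERVEFREQUENCY", fget("$FREQUENCYMHZ", 700.0))
    meta: dict = {}
    if records.get("TITLE"):
        meta["sample_id"] = records["TITLE"]
    for label, key in [
        ("$GROUP", "group"),
        ("$CELLCOUNT", "cell_count"),
        ("$NSCANS", "n_scans"),
        ("$ISOLATIONMETHOD", "isolation_method"),
    ]:
        if label in records and records[label] != "":
            meta[key] = _coerce_scalar(records[label])
    return _sorted_spectrum(x, y, freq, meta)


def write_jcampdx_spectrum(
    s: Spectrum, path, *, timestamps: bool = True
) -> None:
    """Write a single-block real-1D JCAMP-DX (.jdx) file, AFFN encoded.

    The axis is emitted descending (NMR display convention); the reader
    re-sorts ascending, so write/read round-trips are identity.
    """
    path = Path(path)
    ppm = s.ppm[::-1]
    y = s.intensity[::-1]
    lines = [
        f"##TITLE={s.meta.get('sample_id', path.stem)}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NMR SPECTRUM",
        "##DATA CLASS=XYDATA",
        f"##ORIGIN=neutromet {__version__}",
        "##OWNER=",
    ]
    if timestamps:
        lines.append(f"##LONG DATE={datetime.datetime.now().isoformat()}")
    lines += [
        f"##.OBSERVE FREQUENCY={s.frequency_mhz:.10g}",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        "##XFACTOR=1",
        "##YFACTOR=1",
        f"##FIRSTX={ppm[0]:.12g}",
        f"##LASTX={ppm[-1]:.12g}",
        f"##NPOINTS={ppm.size}",
        f"##FIRSTY={y[0]:.17g}",
    ]
    for label, key in [
        ("$GROUP", "group"),
        ("$CELLCOUNT", "cell_count"),
        ("$NSCANS", "n_scans"),
        ("$ISOLATIONMETHOD", "isolation_method"),
    ]:
        if key in s.meta:
            lines.append(f"##{label}={s.meta[key]}")
    lines.append("##XYDATA=(X++(Y..Y))")
    per_line = 4
    for i in range(0, ppm.size, per_line):
        chunk = " ".join(f"{v:.17g}" for v in y[i : i + per_line])
        lines.append(f"{ppm[i]:.12g} {chunk}")
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum(path, format: str = "auto") -> Spectrum:
    """Read a 1D spectrum from JCAMP-DX or two-column tabular text.

    ``format='auto'`` sniffs: a ``##TITLE`` record (or .jdx/.dx suffix)
    selects the JCAMP-DX parser, anything else the tabular one. The axis
    is returned strictly ascending regardless of source ordering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        head = path.read_text()[:512]
        if path.suffix.lower() in (".jdx", ".dx") or "##TITLE" in head:
            format = "jcampdx"
        else:
            format = "tabular"
    if format == "jcampdx":
        return _read_jcampdx_spectrum(path)
    if format == "tabular":
        return _read_tabular_spectrum(path)
    raise ValueError(f"unknown spectrum format {format!r}")


# --------------------------------------------------------------------------
# pattern files
# --------------------------------------------------------------------------


def read_pattern(path) -> PatternFile:
    """Read a pattern file: one bin per row.

    Columns (comma- or tab-delimited): bin_id, left_ppm, right_ppm,
    annotation, metabolite_id (may be empty). A header row is skipped if
    its second field is not numeric. Rows sharing a metabolite_id are
    candidates of one metabolite.
    """
    path = Path(path)
    bins = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        sep = "\t" if "\t" in line else ","
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) < 4:
            raise FormatError(
                f"{path}:{lineno}: expected >=4 columns "
                "(bin_id, left_ppm, right_ppm, annotation[, metabolite_id])"
            )
        try:
            left, right = float(parts[1]), float(parts[2])
        except ValueError:
            if lineno == 1 or not bins:
                continue  # header row
            raise FormatError(f"{path}:{lineno}: non-numeric bin boundaries")
        try:
            bins.append(
                BinDefinition(
                    bin_id=parts[0],
                    left_ppm=left,
                    right_ppm=right,
                    annotation=parts[3] if len(parts) > 3 and parts[3] else "unknown",
                    metabolite_id=parts[4] if len(parts) > 4 else "",
                )
            )
        except InvariantError as exc:
            raise InvariantError(f"{path}:{lineno}: {exc}") from exc
    if not bins:
        raise FormatError(f"{path}: no bin rows found")
    return PatternFile(bins)


def write_pattern(pattern: PatternFile, path, *, timestamps: bool = True) -> None:
    path = Path(path)
    lines = [f"# neutromet pattern v1 (package_version {__version__})"]
    if timestamps:
        lines.append(f"# written: {datetime.datetime.now().isoformat()}")
    lines.append("bin_id\tleft_ppm\tright_ppm\tannotation\tmetabolite_id")
    for b in pattern:
        lines.append(
            f"{b.bin_id}\t{b.left_ppm:.6g}\t{b.right_ppm:.6g}\t{b.annotation}\t{b.metabolite_id}"
        )
    path.write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# feature tables
# --------------------------------------------------------------------------


def write_feature_table(
    table: FeatureTable, path, *, timestamps: bool = True
) -> None:
    """Write a feature table as tab-delimited text with embedded metadata.

    Bin definitions and the processing state are carried in ``#`` header
    lines so a write/read round-trip reconstructs the full object.
    """
    if table.n_samples == 0:
        raise InvariantError("refusing to write a feature table with 0 samples")
    path = Path(path)
    lines = ["# neutromet feature-table v1", f"# package_version: {__version__}"]
    if timestamps:
        lines.append(f"# written: {datetime.datetime.now().isoformat()}")
    lines.append(f"# state: {table.state}")
    meta_cols = list(table.sample_meta.columns)
    lines.append("# meta_columns: " + ",".join(meta_cols))
    for b in table.bins:
        lines.append(
            f"# bin: {b.bin_id}\t{b.left_ppm:.12g}\t{b.right_ppm:.12g}"
            f"\t{b.annotation}\t{b.metabolite_id}"
        )
    header = meta_cols + table.bin_ids
    lines.append("\t".join(header))
    for i in range(table.n_samples):
        meta_vals = [str(table.sample_meta.iloc[i][c]) for c in meta_cols]
        data_vals = [f"{v:.17g}" for v in table.values[i]]
        lines.append("\t".join(meta_vals + data_vals))
    path.write_text("\n".join(lines) + "\n")


def read_feature_table(path) -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`."""
    path = Path(path)
    state = "raw"
    meta_cols: list = []
    bins: list = []
    body: list = []
    for raw in path.read_text().splitlines():
        if raw.startswith("#"):
            stripped = raw[1:].strip()
            if stripped.startswith("state:"):
                state = stripped.split(":", 1)[1].strip()
            elif stripped.startswith("meta_columns:"):
                meta_cols = [
                    c for c in stripped.split(":", 1)[1].strip().split(",") if c
                ]
            elif stripped.startswith("bin:"):
                # trailing fields (empty metabolite_id) survive as empty strings
                parts = stripped.split(":", 1)[1].lstrip().split("\t")
                parts += [""] * (5 - len(parts))
                if len(parts) != 5 or not parts[0]:
                    raise FormatError(f"{path}: malformed bin header line {raw!r}")
                bins.append(
                    BinDefinition(
                        bin_id=parts[0],
                        left_ppm=float(parts[1]),
                        right_ppm=float(parts[2]),
                        annotation=parts[3],
                        metabolite_id=parts[4],
                    )
                )
            continue
        if raw.strip():
            body.append(raw)
    if not body:
        raise FormatError(f"{path}: no header/data rows found")
    header = body[0].split("\t")
    bin_ids = [b.bin_id for b in bins]
    if header[: len(meta_cols)] != meta_cols or header[len(meta_cols):] != bin_ids:
        raise FormatError(f"{path}: header row does not match embedded metadata")
    rows_meta: list = []
    rows_val: list = []
    for line in body[1:]:
        parts = line.split("\t")
        if len(parts) != len(header):
            raise FormatError(f"{path}: row width mismatch: {line!r}")
        rows_meta.append([_coerce_scalar(v) for v in parts[: len(meta_cols)]])
        rows_val.append([float(v) for v in parts[len(meta_cols):]])
    sample_meta = pd.DataFrame(rows_meta, columns=meta_cols)
    return FeatureTable(np.asarray(rows_val), sample_meta, bins, state)


def feature_table_io(table, path, direction: str):
    """Round-trip helper: ``direction='write'`` writes ``table`` to ``path``,
    ``direction='read'`` reads a table back (``table`` ignored)."""
    if direction == "write":
        write_feature_table(table, path)
        return Path(path)
    if direction == "read":
        return read_feature_table(path)
    raise ValueError("direction must be 'write' or 'read'")
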