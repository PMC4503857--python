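"""JCAMP-DX spectrum reader (4.24/5.x subset).

Supports ``##XYDATA=(X++(Y..Y))`` with AFFN numbers and the ASDF
compressed digit forms (SQZ, DIF, DUP), plus ``##XYPOINTS`` and
``##PEAK TABLE`` pair lists.  Raw values are scaled by XFACTOR/YFACTOR;
the x grid of XYDATA comes from FIRSTX/LASTX/NPOINTS.  In DIF mode the
first y of each continuation line is the checkpoint duplicating the
previous line's last y and is dropped, per the standard.
"""

from __future__ import annotations

import re

from ..errors import ParseError
from ..spectra import Spectrum

__all__ = ["read_jcamp"]

# ASDF digit tables
_SQZ = {c: v for v, c in enumerate("@ABCDEFGHI")}          # +0..+9
_SQZ.update({c: -(v + 1) for v, c in enumerate("abcdefghi")})
_DIF = {c: v for v, c in enumerate("%JKLMNOPQR")}          # +0..+9
_DIF.update({c: -(v + 1) for v, c in enumerate("jklmnopqr")})
_DUP = {c: v + 1 for v, c in enumerate("STUVWXYZ")}        # 1..8
_DUP["s"] = 9

_TOKEN_RE = re.compile(r"[@A-Za-z%][0-9.]*|[+-]?[0-9]+(?:\.[0-9]+)?(?:[eE][+-]?[0-9]+)?")


def _parse_labelled(text: str) -> list[tuple[str, str]]:
    """Split into (LABEL, content) records; content keeps its lines."""
    records: list[tuple[str, str]] = []
    label, body = None, []
    for line in text.replace("\r\n", "\n").split("\n"):
        line = line.split("$$")[0]  # inline comments
        if line.startswith("##"):
            if label is not None:
                records.append((label, "\n".join(body)))
            head, _, rest = line[2:].partition("=")
            # normalize: drop spaces/hyphens, uppercase
            label = re.sub(r"[-_ ]", "", head).upper()
            body = [rest.strip()]
        elif label is not None:
            body.append(line)
    if label is not None:
        records.append((label, "\n".join(body)))
    return records


def _decode_asdf_line(line: str) -> tuple[list[float], bool]:
    """Decode one (X++(Y..Y)) data line to raw y values.

    Returns (values, ended_in_dif).  The leading X checkpoint token is
    dropped.  SQZ/DIF/DUP letters switch the token mode; DUP repeats the
    previous token (re-applying its difference when it was a DIF token).
    """
    tokens = _TOKEN_RE.findall(line)
    if not tokens:
        return [], False
    tokens = tokens[1:]  # drop the line's X value
    values: list[float] = []
    last_was_dif = False
    prev_token_value: float | None = None
    prev_token_was_dif = False
    for tok in tokens:
        c = tok[0]
        if c in _DUP:
            if not tok[1:].isspace() and len(tok) > 1 and not tok[1:].isdigit():
                raise ParseError(f"malformed DUP token {tok!r}")
            count = _DUP[c]
            if len(tok) > 1:
                count = int(str(count) + tok[1:])
            if prev_token_value is None:
                raise ParseError("DUP token with no preceding value")
            for _ in range(count - 1):
                if prev_token_was_dif:
                    values.append(values[-1] + prev_token_value)
                else:
                    values.append(prev_token_value)
            last_was_dif = prev_token_was_dif
            continue
        if c in _SQZ:
            value = float(str(_SQZ[c]) + tok[1:]) if tok[1:] else float(_SQZ[c])
            if _SQZ[c] < 0 and tok[1:]:
                value = -float(str(-_SQZ[c]) + tok[1:])
            values.append(value)
            prev_token_value, prev_token_was_dif = value, False
            last_was_dif = False
        elif c in _DIF:
            d = _DIF[c]
            delta = float(str(d) + tok[1:]) if tok[1:] else float(d)
            if d < 0 and tok[1:]:
                delta = -float(str(-d) + tok[1:])
            if not values:
                raise ParseError("DIF token with no preceding y value")
            values.append(values[-1] + delta)
            prev_token_value, prev_token_was_dif = delta, True
            last_was_dif = True
        else:  # AFFN
            values.append(float(tok))
            prev_token_value, prev_token_was_dif = float(tok), False
            last_was_dif = False
    return values, last_was_dif


def _decode_xydata(body: str, xfactor: float, yfactor: float,
                   firstx: float, lastx: float,
                   npoints: int) -> tuple[list[float], list[float]]:
    ys: list[float] = []
    pending_dif = False
    for line in body.split("\n")[1:]:  # first body line is the variable list
        if not line.strip():
            continue
        vals, ended_dif = _decode_asdf_line(line)
        if pending_dif and vals:
            # checkpoint y duplicates the previous line's final y
            check = vals.pop(0)
            if ys and abs(check - ys[-1]) > 1e-6 * max(1.0, abs(ys[-1])):
                raise ParseError(
                    f"DIF checkpoint mismatch: {check} vs {ys[-1]}")
        ys.extend(vals)
        pending_dif = ended_dif
    if npoints and len(ys) != npoints:
        raise ParseError(f"##NPOINTS={npoints} but decoded {len(ys)} points")
    n = len(ys)
    if n == 0:
        raise ParseError("XYDATA block decoded to zero points")
    dx = (lastx - firstx) / (n - 1) if n > 1 else 0.0
    xs = [firstx + i * dx for i in range(n)]
    return xs, [y * yfactor for y in ys]


def _decode_pairs(body: str, xfactor: float,
                  yfactor: float) -> tuple[list[float], list[float]]:
    xs, ys = [], []
    text = " ".join(body.split("\n")[1:])
    for pair in re.split(r"[;]", text):
        nums = re.findall(r"[+-]?[0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?", pair)
        if len(nums) == 0:
            continue
        if len(nums) % 2:
            raise ParseError(f"odd number of values in pair list: {pair!r}")
        for k in range(0, len(nums), 2):
            xs.append(float(nums[k]) * xfactor)
            ys.append(float(nums[k + 1]) * yfactor)
    if not xs:
        raise ParseError("point table decoded to zero points")
    return xs, ys


_KIND_MAP = (("NMR", "nmr"), ("INFRARED", "ir"), ("IR", "ir"),
             ("UV", "uvvis"), ("MASS", "ms"))


def read_jcamp(text: str) -> Spectrum:
    records = _parse_labelled(text)
    labels = {}
    for key, body in records:
        labels.setdefault(key, body)
    if "TITLE" not in labels:
        raise ParseError("missing ##TITLE")

    def num(key: str, default: float | None = None) -> float | None:
        if key not in labels:
            return default
        first = labels[key].split("\n")[0].strip()
        try:
            return float(first)
        except ValueError:
            return default

    xfactor = num("XFACTOR", 1.0)
    yfactor = num("YFACTOR", 1.0)
    if "XYDATA" in labels:
        firstx = num("FIRSTX")
        lastx = num("LASTX")
        if firstx is None or lastx is None:
            raise ParseError("##XYDATA requires ##FIRSTX and ##LASTX")
        npoints = int(num("NPOINTS", 0) or 0)
        xs, ys = _decode_xydata(labels["XYDATA"], xfactor, yfactor,
                                firstx, lastx, npoints)
    elif "XYPOINTS" in labels:
        xs, ys = _decode_pairs(labels["XYPOINTS"], xfactor, yfactor)
    elif "PEAKTABLE" in labels:
        xs, ys = _decode_pairs(labels["PEAKTABLE"], xfactor, yfactor)
    else:
        raise ParseError("no ##XYDATA, ##XYPOINTS or ##PEAK TABLE block")

    datatype = labels.get("DATATYPE", "").split("\n")[0].upper()
    kind = "nmr"
    for key, value in _KIND_MAP:
        if key in datatype:
            kind = value
            break
    if "PEAKTABLE" in labels and "MASS" in datatype:
        kind = "ms"
    meta = {k: v.split("\n")[0] for k, v in labels.items()
            if k not in ("XYDATA", "XYPOINTS", "PEAKTABLE")}
    return Spectrum(
        x=xs, y=ys, kind=kind,
        x_units=labels.get("XUNITS", "").split("\n")[0],
        y_units=labels.get("YUNITS", "").split("\n")[0],
        title=labels["TITLE"].split("\n")[0],
        metadata=meta)
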