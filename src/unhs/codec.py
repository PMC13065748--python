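"""Bijective base-35 codec for UNHS codes.

A UNHS code is the bijective base-35 rendering of a positive sequential
identifier over the 35-symbol alphabet ``A..Z`` (values 1..26) followed by
``1..9`` (values 27..35) — there is no zero symbol, so every positive
integer has exactly one representation — plus a trailing check letter
computed as ``26 - (n mod 26)`` mapped to the corresponding uppercase
letter (``Z`` when n is divisible by 26).  National extension codes append
``.k`` (k >= 1, no leading zeros) after the check letter; the suffix never
participates in the checksum.

Example: identifier 22718 = 18*35^2 + 19*35 + 3 -> core ``RSC``; check
value 26 - (22718 mod 26) = 6 -> ``F``; full code ``RSCF``.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "ALPHABET",
    "BASE",
    "CodecError",
    "ParseError",
    "UnhsCode",
    "ValidationResult",
    "symbol_value",
    "value_symbol",
    "encode_identifier",
    "decode_core",
    "check_value",
    "check_digit",
    "make_code",
    "parse_code",
    "validate_code",
]

#: The 35 core symbols in value order: A..Z are 1..26, digits 1..9 are 27..35.
#: "0" is deliberately absent — bijective numeration has no zero digit.
ALPHABET: str = string.ascii_uppercase + "123456789"
BASE: int = len(ALPHABET)  # 35

_SYMBOL_TO_VALUE = {c: i + 1 for i, c in enumerate(ALPHABET)}
_VALUE_TO_SYMBOL = {i + 1: c for i, c in enumerate(ALPHABET)}

#: Modulus of the check-digit rule; check letters span A..Z only.
CHECK_MODULUS: int = 26


class CodecError(ValueError):
    """Invalid input to a strict codec construction operation."""


class ParseError(CodecError):
    """A code string that does not match the UNHS grammar.

    Attributes
    ----------
    position : int
        0-based index of the first offending character.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


def symbol_value(c: str) -> int:
    """Value (1..35) of one core alphabet symbol.

    Input is uppercased first; ``"0"`` and any character outside
    ``A-Z1-9`` are rejected.
    """
    if not isinstance(c, str) or len(c) != 1:
        raise CodecError(f"expected a single character, got {c!r}")
    cu = c.upper()
    try:
        return _SYMBOL_TO_VALUE[cu]
    except KeyError:
        raise CodecError(
            f"character {c!r} is not in the UNHS alphabet [A-Z1-9]"
        ) from None


def value_symbol(v: int) -> str:
    """Inverse of :func:`symbol_value`: the symbol for value 1..35."""
    try:
        return _VALUE_TO_SYMBOL[v]
    except KeyError:
        raise CodecError(f"value {v!r} is outside 1..{BASE}") from None


def encode_identifier(n: int) -> str:
    """Bijective base-35 core string for identifier ``n`` (n >= 1).

    Digits are 1..35; the least-significant digit is
    ``((n - 1) mod 35) + 1``, and the quotient recurses until exhausted.
    """
    _require_identifier(n)
    symbols = []
    while n > 0:
        d = (n - 1) % BASE + 1
        symbols.append(_VALUE_TO_SYMBOL[d])
        n = (n - d) // BASE
    return "".join(reversed(symbols))


def decode_core(core: str) -> int:
    """Positive identifier encoded by a core string (exact inverse of
    :func:`encode_identifier`)."""
    if not core:
        raise CodecError("empty core string")
    n = 0
    for c in core:
        n = n * BASE + symbol_value(c)
    return n


def check_value(n: int) -> int:
    """Numeric check value ``26 - (n mod 26)``, in 1..26."""
    _require_identifier(n)
    return CHECK_MODULUS - n % CHECK_MODULUS


def check_digit(n: int) -> str:
    """Check letter for identifier ``n``: the ``check_value(n)``-th
    uppercase letter (``Z`` when n is divisible by 26)."""
    return string.ascii_uppercase[check_value(n) - 1]


@dataclass(frozen=True)
class UnhsCode:
    """A parsed UNHS code: core symbols, check letter, optional extension."""

    core: str
    check: str
    extension: Optional[int] = None

    @property
    def canonical_text(self) -> str:
        text = self.core + self.check
        if self.extension is not None:
            text += f".{self.extension}"
        return text

    @property
    def base_text(self) -> str:
        """Code without the extension suffix (the parent code for extensions)."""
        return self.core + self.check

    @property
    def identifier(self) -> int:
        """Identifier recovered from the core (checksum not verified here)."""
        return decode_core(self.core)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_text


def make_code(n: int) -> UnhsCode:
    """Full code for identifier ``n``: core plus check letter, no extension."""
    _require_identifier(n)
    return UnhsCode(core=encode_identifier(n), check=check_digit(n))


def parse_code(text: str) -> UnhsCode:
    """Parse (but do not checksum-verify) a code string.

    Accepts ``CORE+CHECK`` optionally followed by ``.`` and a positive
    integer with no leading zero.  Input is uppercased.  Raises
    :class:`ParseError` carrying the position of the first error.
    """
    if not isinstance(text, str):
        raise CodecError(f"expected a string, got {type(text).__name__}")
    text = text.strip().upper()
    if not text:
        raise ParseError("empty code", 0)

    dot = text.find(".")
    body = text if dot < 0 else text[:dot]

    if len(body) < 2:
        raise ParseError("code needs at least one core symbol and a check letter", len(body))
    for i, c in enumerate(body):
        if c not in _SYMBOL_TO_VALUE:
            raise ParseError(f"illegal character {c!r}", i)
    check = body[-1]
    if check not in string.ascii_uppercase:
        raise ParseError(f"check character {check!r} must be a letter A-Z", len(body) - 1)

    extension: Optional[int] = None
    if dot >= 0:
        suffix = text[dot + 1:]
        if not suffix:
            raise ParseError("empty extension suffix after '.'", dot + 1)
        if not suffix.isdigit():
            bad = next(i for i, c in enumerate(suffix) if not c.isdigit())
            raise ParseError(f"non-numeric extension character {suffix[bad]!r}", dot + 1 + bad)
        if suffix[0] == "0":
            raise ParseError("extension suffix has a leading zero", dot + 1)
        extension = int(suffix)

    return UnhsCode(core=body[:-1], check=check, extension=extension)


@dataclass(frozen=True)
class ValidationResult:
    """In-band outcome of :func:`validate_code`."""

    valid: bool
    identifier: Optional[int] = None
    extension: Optional[int] = None
    reason: Optional[str] = None


def validate_code(text: str) -> ValidationResult:
    """Total validation: parse plus checksum verification.

    Never raises; all failures come back as ``valid=False`` with a reason.
    The extension suffix is ignored by the checksum.  On success the
    recovered numeric identifier is reported.
    """
    try:
        code = parse_code(text)
    except CodecError as exc:
        return ValidationResult(valid=False, reason=str(exc))
    n = decode_core(code.core)
    expected = check_digit(n)
    if code.check != expected:
        return ValidationResult(
            valid=False,
            identifier=n,
            extension=code.extension,
            reason=(
                f"checksum mismatch: identifier {n} requires check letter "
                f"{expected!r}, found {code.check!r}"
            ),
        )
    return ValidationResult(valid=True, identifier=n, extension=code.extension)


def _require_identifier(n: int) -> None:
    if not isinstance(n, int) or isinstance(n, bool):
        raise CodecError(f"identifier must be an integer, got {type(n).__name__}")
    if n < 1:
        raise CodecError(f"identifier must be >= 1, got {n} (no representation of 0)")
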