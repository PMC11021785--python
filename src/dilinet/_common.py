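"""Shared error types, rounding and name-normalization helpers."""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

logger = logging.getLogger("dilinet")


class DilinetError(Exception):
    """Base class for all package errors."""


class ConfigError(DilinetError, ValueError):
    """Invalid configuration; the message names the offending field."""


class SchemaError(DilinetError):
    """An input file is missing mandatory columns."""


class ParseError(DilinetError):
    """A row or line of an input file could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class IntegrityError(DilinetError):
    """Cross-reference violation inside a dictionary or dataset."""


class TermLookupError(DilinetError, KeyError):
    """A requested code does not exist at the stated hierarchy level."""

    def __init__(self, level: str, code: str):
        super().__init__(f"unknown {level} code: {code!r}")
        self.level = level
        self.code = code


class DegenerateMarginError(DilinetError):
    """A 2x2 table has an empty drug or comparator margin."""


class StageError(DilinetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (half-up), as printed tables do.

    Python's built-in round() is banker's rounding; regulatory tables
    conventionally round 0.005 up to 0.01.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


#: Salt/ester suffixes stripped from drug names before matching. FAERS
#: verbatim names frequently carry the salt form of the active moiety.
DEFAULT_SALT_SUFFIXES = (
    "hydrochloride",
    "succinate",
    "mesylate",
    "maleate",
    "tartrate",
    "citrate",
    "phosphate",
    "sodium",
    "besylate",
    "fumarate",
    "hcl",
)


def normalize_drug_name(
    name: str,
    synonyms: dict[str, str] | None = None,
    salt_suffixes: tuple[str, ...] = DEFAULT_SALT_SUFFIXES,
) -> str:
    """Case-fold, trim, strip trailing salt suffixes, then apply synonyms.

    ``synonyms`` maps alias -> canonical (both matched case-insensitively),
    e.g. brand name KISQALI -> ribociclib.
    """
    s = " ".join(name.strip().casefold().split())
    parts = s.split(" ")
    while len(parts) > 1 and parts[-1] in salt_suffixes:
        parts = parts[:-1]
    s = " ".join(parts)
    if synonyms:
        s = synonyms.get(s, s)
    return s


def normalize_gene_symbol(symbol: str, aliases: dict[str, str] | None = None) -> str:
    """Trim, uppercase, and alias-map a gene symbol."""
    s = symbol.strip().upper()
    if aliases:
        s = aliases.get(s, s)
    return s
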