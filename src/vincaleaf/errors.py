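"""Exception hierarchy shared across the package."""


class VincaleafError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(VincaleafError, ValueError):
    """A value violates a precondition (negative count, empty sample, ...)."""


class UndefinedIndexError(VincaleafError, ZeroDivisionError):
    """An index is undefined because its denominator is zero.

    Raised instead of silently returning 0 so that "no stomata observed"
    (SD = 0, E > 0, SI = 0) stays distinguishable from "no data at all"
    (SD = E = 0).
    """


class InconsistentMeasurementError(VincaleafError, ValueError):
    """A tissue thickness exceeds the total leaf thickness it is part of."""


class ClassificationError(VincaleafError):
    """Pixels could not be assigned to any legend class under policy='error'."""

    def __init__(self, n_unresolved: int, example_coord: tuple[int, int],
                 example_color: tuple[int, int, int]):
        self.n_unresolved = n_unresolved
        self.example_coord = example_coord
        self.example_color = example_color
        super().__init__(
            f"{n_unresolved} pixel(s) match no legend class; first at "
            f"(row={example_coord[0]}, col={example_coord[1]}) with RGB "
            f"{example_color}"
        )


class NoMesophyllError(VincaleafError):
    """An image contains no mesophyll pixels (cell + intercellular = 0)."""


class GenerationError(VincaleafError):
    """A synthetic generator could not reach its target within its attempt budget."""


class ParseError(VincaleafError, ValueError):
    """A CSV table violates its schema; names the column and row."""

    def __init__(self, message: str, path=None, row: int | None = None,
                 column: str | None = None):
        self.path = path
        self.row = row
        self.column = column
        loc = []
        if path is not None:
            loc.append(str(path))
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        prefix = f"[{', '.join(loc)}] " if loc else ""
        super().__init__(prefix + message)


class ConfigError(VincaleafError):
    """Pipeline configuration problem detected before any computation."""
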