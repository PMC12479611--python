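"""Ordered threshold schemes mapping index values to heat-stress levels.

A :class:`ClassificationScheme` is a named, ordered list of bands.  Each band
carries a lower bound (inclusive), a severity level, a short label and the
occupational-response guidance attached to that level.  A value classifies
into the last band whose lower bound does not exceed it, so band edges are
lower-inclusive / upper-exclusive and every finite value receives exactly
one level.

Three schemes are bundled (``humidex_1`` for acclimatised persons,
``humidex_2`` for unacclimatised persons, and ``nws_heat_index``); their
numeric thresholds live in ``data/schemes.yaml``, not in code, and the
Humidex transcription is verified at load time against the published worked
classifications that anchor it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError

__all__ = [
    "Band",
    "ClassificationScheme",
    "classify",
    "guidance_for",
    "load_schemes",
    "default_schemes",
]


@dataclass(frozen=True)
class Band:
    """One classification band: applies from ``lower_bound`` (inclusive)."""

    lower_bound: float
    level: int
    label: str
    guidance: str


@dataclass(frozen=True)
class ClassificationScheme:
    """An ordered, validated set of heat-stress bands.

    Parameters
    ----------
    name : str
        Scheme identifier (e.g. ``"humidex_1"``).
    index : str
        Name of the index column the scheme applies to
        (``"humidex_c"`` or ``"heat_index_c"``).
    bands : sequence of Band
        Strictly increasing lower bounds and levels; the first band must
        start at ``-inf``.
    """

    name: str
    index: str
    bands: tuple[Band, ...]
    _inner_bounds: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if not self.bands:
            raise ConfigurationError(f"scheme {self.name!r}: no bands")
        if self.bands[0].lower_bound != float("-inf"):
            raise ConfigurationError(
                f"scheme {self.name!r}: first band must start at -inf, "
                f"got {self.bands[0].lower_bound}"
            )
        bounds = [b.lower_bound for b in self.bands]
        levels = [b.level for b in self.bands]
        for i in range(1, len(self.bands)):
            if not bounds[i] > bounds[i - 1]:
                raise ConfigurationError(
                    f"scheme {self.name!r}: band {i} lower bound "
                    f"{bounds[i]} does not exceed previous bound {bounds[i - 1]}"
                )
            if not levels[i] > levels[i - 1]:
                raise ConfigurationError(
                    f"scheme {self.name!r}: band {i} level {levels[i]} does "
                    f"not exceed previous level {levels[i - 1]}"
                )
        object.__setattr__(self, "_inner_bounds", np.asarray(bounds[1:], dtype=float))

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(b.level for b in self.bands)

    def classify(self, value):
        """Level(s) for a value or array of values (lower-inclusive edges)."""
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ConfigurationError(
                f"scheme {self.name!r}: cannot classify non-finite value"
            )
        idx = np.searchsorted(self._inner_bounds, arr, side="right")
        levels = np.asarray(self.levels, dtype=int)[idx]
        if np.isscalar(value) or np.ndim(value) == 0:
            return int(levels)
        return levels

    def band_for_level(self, level: int) -> Band:
        for band in self.bands:
            if band.level == int(level):
                return band
        raise KeyError(f"scheme {self.name!r} has no level {level}")

    def guidance_for(self, level: int) -> str:
        """Occupational-response text attached to ``level``."""
        return self.band_for_level(level).guidance

    def label_for(self, level: int) -> str:
        return self.band_for_level(level).label


def classify(value, scheme: ClassificationScheme):
    """Functional alias for :meth:`ClassificationScheme.classify`."""
    return scheme.classify(value)


def guidance_for(level: int, scheme: ClassificationScheme) -> str:
    """Functional alias for :meth:`ClassificationScheme.guidance_for`."""
    return scheme.guidance_for(level)


def _scheme_from_entry(name: str, entry: Mapping) -> ClassificationScheme:
    try:
        raw_bands: Sequence[Mapping] = entry["bands"]
    except (KeyError, TypeError):
        raise ConfigurationError(f"scheme {name!r}: missing 'bands' list") from None
    bands = []
    for i, raw in enumerate(raw_bands):
        try:
            bands.append(
                Band(
                    lower_bound=float(raw["lower_bound"]),
                    level=int(raw["level"]),
                    label=str(raw.get("label", f"level {raw['level']}")),
                    guidance=str(raw.get("guidance", "")),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"scheme {name!r}: malformed band {i}: {exc}") from exc
    return ClassificationScheme(
        name=name, index=str(entry.get("index", "humidex_c")), bands=tuple(bands)
    )


# Published worked classifications anchoring the Humidex transcription; they
# are re-checked every time the bundled file is loaded.
_BUNDLED_SELF_CHECKS = {
    "humidex_1": [(33.82, 1), (42.26, 3), (24.50, 0)],
    "humidex_2": [(33.82, 2), (42.26, 6), (24.50, 0)],
}


def load_schemes(path: str | Path | None = None) -> dict[str, ClassificationScheme]:
    """Load classification schemes from YAML (bundled defaults if no path).

    Raises
    ------
    ConfigurationError
        On non-monotone bounds/levels, a missing ``-inf`` opening band, or —
        for the bundled file — a transcription that violates the published
        worked classifications.
    """
    if path is None:
        text = (resources.files("heatdex") / "data" / "schemes.yaml").read_text()
    else:
        text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"unparseable scheme file: {exc}") from exc
    if not isinstance(doc, Mapping) or "schemes" not in doc:
        raise ConfigurationError("scheme file must contain a top-level 'schemes' mapping")
    schemes = {
        name: _scheme_from_entry(name, entry) for name, entry in doc["schemes"].items()
    }
    if path is None:
        for name, checks in _BUNDLED_SELF_CHECKS.items():
            for value, expected in checks:
                got = schemes[name].classify(value)
                if got != expected:
                    raise ConfigurationError(
                        f"bundled scheme {name!r} misclassifies {value}: "
                        f"got level {got}, transcription anchor requires {expected}"
                    )
    return schemes


_DEFAULTS_CACHE: dict[str, ClassificationScheme] | None = None


def default_schemes() -> dict[str, ClassificationScheme]:
    """The three bundled schemes, loaded once and cached."""
    global _DEFAULTS_CACHE
    if _DEFAULTS_CACHE is None:
        _DEFAULTS_CACHE = load_schemes()
    return dict(_DEFAULTS_CACHE)
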