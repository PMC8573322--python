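"""Exception types shared across the package."""

from __future__ import annotations

__all__ = [
    "SearchShiftError",
    "StimulusError",
    "SchemaError",
    "ConfigError",
    "DegenerateDataError",
    "SeparationError",
    "InsufficientClustersError",
]


class SearchShiftError(Exception):
    """Base class for package errors."""


class StimulusError(SearchShiftError, RuntimeError):
    """Stimulus generation could not satisfy its constraints."""


class SchemaError(SearchShiftError, ValueError):
    """A table violates its declared column schema."""


class ConfigError(SearchShiftError, ValueError):
    """A pipeline configuration is invalid."""


class DegenerateDataError(SearchShiftError, ValueError):
    """Input data admit no meaningful estimate (constant response, equal EVs, ...)."""


class SeparationError(DegenerateDataError):
    """The binary response is constant; a logistic model cannot be fit."""


class InsufficientClustersError(DegenerateDataError):
    """Too few participants for cluster-level resampling or mixed-model fitting."""
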