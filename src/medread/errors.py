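"""Typed errors shared across the pipeline."""


class MedreadError(Exception):
    """Base class for all package errors."""


class EmptyDocument(MedreadError):
    """No visible text survived HTML extraction."""


class DegenerateText(MedreadError):
    """Zero sentences or zero words: the document cannot be scored."""


class InsufficientCorpus(MedreadError):
    """Fewer than two documents: sample statistics are undefined."""


class EmptySeries(MedreadError):
    """A time series with no observations."""


class DegenerateVariance(MedreadError):
    """A constant series: Pearson correlation is undefined."""


class MisalignedYears(MedreadError):
    """Two annual series whose year vectors differ."""


class InfeasibleSpec(MedreadError):
    """A synthetic-data specification with contradictory targets."""
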