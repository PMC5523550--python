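"""Exception hierarchy shared across the pipeline."""


class StressRegulonError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(StressRegulonError):
    """Invalid simulation or analysis configuration."""


class LoadError(StressRegulonError):
    """Malformed or inconsistent input file."""


class ContrastError(StressRegulonError):
    """A requested treated/untreated contrast cannot be formed."""


class DegenerateContrastError(ContrastError):
    """All per-gene differences are zero; the D1 denominator vanishes."""


class OntologyError(StressRegulonError):
    """Ontology graph violates structural requirements (e.g. a cycle)."""
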