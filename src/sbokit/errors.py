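"""Exception hierarchy for sbokit."""


class SbokitError(Exception):
    """Base class for all sbokit errors."""


class ModelParseError(SbokitError):
    """The input file is not valid SBML Level 3."""


class AssignmentTargetError(SbokitError):
    """An assignment references an entity id that does not exist in the model."""

    def __init__(self, unknown_ids):
        self.unknown_ids = list(unknown_ids)
        super().__init__(
            "assignments reference unknown entity ids: " + ", ".join(self.unknown_ids)
        )


class OntologyError(SbokitError):
    """The ontology file is malformed (e.g. the is-a graph contains a cycle)."""


class ConfigurationError(SbokitError):
    """A configured label/id pair does not resolve against the pinned ontology."""


class TriageError(SbokitError):
    """A reaction cannot be classified (degenerate: no participants)."""


class ContractViolationError(SbokitError):
    """An operation was called on an entity outside its contract."""


class ReportError(SbokitError):
    """Before/after documents do not describe the same entity sets."""
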