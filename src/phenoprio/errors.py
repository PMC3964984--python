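"""Exception hierarchy.

Data errors (bad input files, referential violations) and lookup errors
(unknown ids, unresolvable labels) are kept distinct so callers — the CLI in
particular — can map them to different exit codes.
"""

from __future__ import annotations


class PhenoprioError(Exception):
    """Base class for all package errors."""


class OntologyParseError(PhenoprioError):
    """Malformed or structurally invalid OBO input."""


class CycleError(OntologyParseError):
    def __init__(self, cycle_ids):
        self.cycle_ids = sorted(set(cycle_ids))
        super().__init__(f"is_a cycle involving terms: {', '.join(self.cycle_ids)}")


class DuplicateTermError(OntologyParseError):
    def __init__(self, term_ids):
        self.term_ids = sorted(set(term_ids))
        super().__init__(f"duplicate term id(s): {', '.join(self.term_ids)}")


class DanglingReferenceError(OntologyParseError):
    def __init__(self, missing_ids):
        self.missing_ids = sorted(set(missing_ids))
        super().__init__(f"is_a reference(s) to unknown term(s): {', '.join(self.missing_ids)}")


class TermLookupError(PhenoprioError, KeyError):
    """Unknown term id."""

    def __init__(self, term_id):
        self.term_id = term_id
        super().__init__(f"unknown term id: {term_id!r}")


class LabelNotFoundError(PhenoprioError):
    def __init__(self, label):
        self.label = label
        super().__init__(f"no term with name or synonym matching {label!r}")


class AmbiguousLabelError(PhenoprioError):
    """A label matched several terms; candidates are reported, not chosen."""

    def __init__(self, label, candidates):
        self.label = label
        self.candidates = sorted(candidates)
        super().__init__(
            f"label {label!r} is ambiguous between: {', '.join(self.candidates)}"
        )


class QueryParseError(PhenoprioError):
    def __init__(self, message, position=None):
        self.position = position
        at = f" at position {position}" if position is not None else ""
        super().__init__(f"{message}{at}")


class AtomResolutionError(PhenoprioError):
    """A query atom's label could not be resolved in its namespace."""


class StoreValidationError(PhenoprioError):
    """Referential or format errors while loading an annotation store.

    All offending records are collected and reported together.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid store:\n" + "\n".join(f"  - {p}" for p in self.problems))


class DomainError(PhenoprioError, ValueError):
    """Statistical parameters outside their valid domain."""


class UndefinedProbabilityError(PhenoprioError):
    """Conditioning on an empty gene set."""


class UnanalyzableDiseaseError(PhenoprioError):
    """No feature of the disease could be mapped into the target vocabulary."""

    def __init__(self, disease_id):
        self.disease_id = disease_id
        super().__init__(f"disease {disease_id!r}: no feature maps to the target ontology")
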