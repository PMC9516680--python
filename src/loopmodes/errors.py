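"""Structured exceptions raised across the package."""


class LoopModesError(Exception):
    """Base class for all loopmodes errors."""


class PDBFormatError(LoopModesError):
    """Input PDB file violates the supported dialect (e.g. insertion codes)."""


class MissingAtomError(LoopModesError):
    """A required backbone atom is absent from the requested residue range."""

    def __init__(self, chain: str, resseq: int, atname: str):
        self.chain = chain
        self.resseq = resseq
        self.atname = atname
        super().__init__(
            f"missing backbone atom {atname!r} in residue {chain}:{resseq}"
        )


class ChainBreakError(LoopModesError):
    """Peptide bond C-N distance exceeds the covalent threshold inside the loop."""


class DegenerateGeometryError(LoopModesError):
    """Collinear or otherwise degenerate atom geometry."""


class ConstraintRankError(LoopModesError):
    """The closure constraint Jacobian is rank deficient at equilibrium."""


class SolverError(LoopModesError):
    """Eigensolver failure, with condition diagnostics in the message."""
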