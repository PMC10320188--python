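"""Shared druggability-evidence vocabulary.

Altered genes are classified by how a drug can act on them: direct
targets, biomarkers of response, genetic dependencies (selective
vulnerabilities of the alteration context) and druggable downstream
pathway members.
"""

from __future__ import annotations

import enum


class EvidenceClass(enum.Enum):
    DIRECT_TARGET = "DIRECT_TARGET"
    BIOMARKER = "BIOMARKER"
    GENETIC_DEPENDENCY = "GENETIC_DEPENDENCY"
    PATHWAY_MEMBER = "PATHWAY_MEMBER"
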