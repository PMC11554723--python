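"""Published correction equations and cutoffs for the Italian adult norms.

These constants transcribe the normative artifacts printed with the 2024
Italian norms for the Corsi Span (CS), SupraSpan Learning (CSSL) and
SupraSpan Recall (CSSR): the three demographic correction equations, the
age/education(/span) lattice of the printed correction grids, and the
Equivalent-Score cutoffs on the adjusted-score scale for the n = 340
normative sample.  They are inputs a clinician would copy from the published
tables, not quantities this package estimates.
"""

from __future__ import annotations

from .norming import CorrectionEquation, CorrectionTerm
from .transforms import TransformSpec

__all__ = [
    "CS_EQUATION",
    "CSSL_EQUATION",
    "CSSR_EQUATION",
    "PUBLISHED_EQUATIONS",
    "GRID_AGES",
    "GRID_EDUCATIONS",
    "GRID_SPANS",
    "NORMATIVE_N",
    "ES_CUTOFFS",
]

#: Adjusted CS = raw + 0.7616*(ln(age) - 3.864) - 0.4229*(sqrt(edu) - 3.555)
CS_EQUATION = CorrectionEquation(
    dependent="cs",
    terms=[
        CorrectionTerm("age", TransformSpec("log", 3.864), 0.7616),
        CorrectionTerm("education", TransformSpec("sqrt", 3.555), -0.4229),
    ],
    r_squared=0.24,
    n=340,
)

#: Adjusted CSSL = raw + 0.841*(sqrt(age) - 7.044) - 2.852*(sqrt(edu) - 3.555)
#: - 8.855*(sqrt(span) - 2.218)
CSSL_EQUATION = CorrectionEquation(
    dependent="cssl",
    terms=[
        CorrectionTerm("age", TransformSpec("sqrt", 7.044), 0.841),
        CorrectionTerm("education", TransformSpec("sqrt", 3.555), -2.852),
        CorrectionTerm("span", TransformSpec("sqrt", 2.218), -8.855),
    ],
    r_squared=0.34,
    n=340,
)

#: Adjusted CSSR = raw + 0.0747*(sqrt(age) - 7.044) - 0.271*(ln(edu) - 2.497)
#: - 0.491*(ln(span) - 1.582)
CSSR_EQUATION = CorrectionEquation(
    dependent="cssr",
    terms=[
        CorrectionTerm("age", TransformSpec("sqrt", 7.044), 0.0747),
        CorrectionTerm("education", TransformSpec("log", 2.497), -0.271),
        CorrectionTerm("span", TransformSpec("log", 1.582), -0.491),
    ],
    r_squared=0.22,
    n=340,
)

PUBLISHED_EQUATIONS = {"cs": CS_EQUATION, "cssl": CSSL_EQUATION, "cssr": CSSR_EQUATION}

#: Axes of the printed correction grids.
GRID_AGES = (20, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85)
GRID_EDUCATIONS = (5, 8, 13, 16, 18, 21)
GRID_SPANS = (2, 3, 4, 5, 6, 7, 8)

#: Size of the published normative sample (tolerance ranks 11 and 24).
NORMATIVE_N = 340

#: Published Equivalent-Score boundaries on the adjusted-score scale:
#: (OTL = ES0 upper bound, ES1 upper, ES2 upper, median = ES3 upper); the
#: inner tolerance limit is listed alongside.
ES_CUTOFFS = {
    "cs": {"otl": 3.43, "es1": 4.21, "es2": 4.52, "median": 4.97, "itl": 3.70},
    "cssl": {"otl": 6.75, "es1": 12.67, "es2": 16.63, "median": 19.37, "itl": 9.93},
    "cssr": {"otl": 0.16, "es1": 0.65, "es2": 0.97, "median": 1.24, "itl": 0.37},
}
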