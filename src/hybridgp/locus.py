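"""Exact single- and two-locus theory for hybrids of two inbred-line pools.

The hybrid population mates gametes from group 1 (alleles B1/b1, frequency
p1 of B1) with gametes from group 2 (B2/b2, frequency p2).  Genotypic values
under additive-plus-dominance gene action are::

    G(B1B2) = a1 + a2     G(B1b2) = a1 + d
    G(b1B2) = a2 + d      G(b1b2) = 0

Every statistical quantity here — average allele effects, substitution
effects, gamete additive values, dominance deviations, component variances —
is obtained both from the closed forms and by exhaustive enumeration over
genotype classes, and the two routes must agree.  The key closed forms:

    E(G)   = p1 a1 + p2 a2 + (p1 q2 + q1 p2) d
    alpha1 = a1 + (q2 - p2) d           (substitution effect, group 1)
    alpha2 = a2 + (q1 - p1) d
    gA1    = { q1 alpha1, -p1 alpha1 }  for gametes B1, b1   (= z1 alpha1)
    gD     = { -2 q1 q2 d, 2 q1 p2 d, 2 p1 q2 d, -2 p1 p2 d } (= w d)
    varA1  = p1 q1 alpha1^2,  varA2 = p2 q2 alpha2^2,
    varD   = 4 p1 q1 p2 q2 d^2

and the decomposition is orthogonal: components have zero mean, zero
pairwise covariance and variances that add exactly to the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LocusSpec",
    "LocusDecomposition",
    "decompose_locus",
    "verify_substitution_definition",
    "dominance_deviation_by_subtraction",
    "two_locus_epistatic_enumeration",
    "genotypic_variance_partition",
]

# hybrid genotype classes in canonical order
CLASSES = ("B1B2", "B1b2", "b1B2", "b1b2")


@dataclass
class LocusSpec:
    """Functional parameters of one biallelic locus.

    a1, a2: functional additive effects of B1 (group 1) and B2 (group 2);
    d: functional dominance value of both heterozygotes; p1, p2: B-allele
    frequencies in the two groups.  Boundary frequencies (0 or 1) are legal
    and give zero-variance components.
    """

    a1: float
    a2: float
    d: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        for name in ("p1", "p2"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p!r} outside [0, 1]")

    @property
    def q1(self) -> float:
        return 1.0 - self.p1

    @property
    def q2(self) -> float:
        return 1.0 - self.p2

    def class_frequencies(self) -> np.ndarray:
        """Ideal hybrid population: gametes unite at random across groups."""
        return np.array([
            self.p1 * self.p2, self.p1 * self.q2,
            self.q1 * self.p2, self.q1 * self.q2,
        ])

    def genotypic_values(self) -> np.ndarray:
        return np.array([
            self.a1 + self.a2, self.a1 + self.d,
            self.a2 + self.d, 0.0,
        ])


@dataclass
class LocusDecomposition:
    """Orthogonal statistical decomposition of one locus in the hybrid population."""

    mean: float
    alpha_B1: float
    alpha_b1: float
    alpha_B2: float
    alpha_b2: float
    alpha1: float
    alpha2: float
    gA1: dict[str, float] = field(default_factory=dict)  # per gamete B1/b1
    gA2: dict[str, float] = field(default_factory=dict)  # per gamete B2/b2
    gD: dict[str, float] = field(default_factory=dict)   # per genotype class
    varA1: float = 0.0
    varA2: float = 0.0
    varD: float = 0.0
    varTotal: float = 0.0


def decompose_locus(L: LocusSpec) -> LocusDecomposition:
    """Full statistical decomposition of one locus, checked by enumeration.

    The component variances are computed by enumerating the four genotype
    classes with ideal-population frequencies; they coincide with the closed
    forms p1 q1 alpha1^2, p2 q2 alpha2^2 and 4 p1 q1 p2 q2 d^2.
    """
    p1, q1, p2, q2, d = L.p1, L.q1, L.p2, L.q2, L.d
    freq = L.class_frequencies()
    G = L.genotypic_values()
    mean = float(freq @ G)

    alpha1 = L.a1 + (q2 - p2) * d
    alpha2 = L.a2 + (q1 - p1) * d
    dec = LocusDecomposition(
        mean=mean,
        alpha_B1=q1 * alpha1, alpha_b1=-p1 * alpha1,
        alpha_B2=q2 * alpha2, alpha_b2=-p2 * alpha2,
        alpha1=alpha1, alpha2=alpha2,
        gA1={"B1": q1 * alpha1, "b1": -p1 * alpha1},
        gA2={"B2": q2 * alpha2, "b2": -p2 * alpha2},
        gD={
            "B1B2": -2 * q1 * q2 * d, "B1b2": 2 * q1 * p2 * d,
            "b1B2": 2 * p1 * q2 * d, "b1b2": -2 * p1 * p2 * d,
        },
    )

    # enumeration over the four classes: each class determines its gametes
    a1_code = np.array([dec.gA1["B1"], dec.gA1["B1"], dec.gA1["b1"], dec.gA1["b1"]])
    a2_code = np.array([dec.gA2["B2"], dec.gA2["b2"], dec.gA2["B2"], dec.gA2["b2"]])
    d_code = np.array([dec.gD[c] for c in CLASSES])
    dec.varA1 = float(freq @ a1_code**2) - float(freq @ a1_code) ** 2
    dec.varA2 = float(freq @ a2_code**2) - float(freq @ a2_code) ** 2
    dec.varD = float(freq @ d_code**2) - float(freq @ d_code) ** 2
    dec.varTotal = float(freq @ G**2) - mean**2
    return dec


def verify_substitution_definition(L: LocusSpec, atol: float = 1e-12) -> tuple[bool, dict[str, float]]:
    """Check that three independent routes to the substitution effect agree.

    Route 1 (substitution experiment): replace b1 by B1 in the genotypes
    where b1 occurs — alpha1 = p2 [G(B1B2) - G(b1B2)] + q2 [G(B1b2) - G(b1b2)].
    Route 2 (difference of average allele effects): alpha1 = alphaB1 - alphab1.
    Route 3 (closed form): alpha1 = a1 + (q2 - p2) d.  Analogous for group 2.
    """
    dec = decompose_locus(L)
    G = dict(zip(CLASSES, L.genotypic_values()))
    report = {
        "alpha1_substitution": L.p2 * (G["B1B2"] - G["b1B2"]) + L.q2 * (G["B1b2"] - G["b1b2"]),
        "alpha1_avg_effect_diff": dec.alpha_B1 - dec.alpha_b1,
        "alpha1_closed_form": L.a1 + (L.q2 - L.p2) * L.d,
        "alpha2_substitution": L.p1 * (G["B1B2"] - G["B1b2"]) + L.q1 * (G["b1B2"] - G["b1b2"]),
        "alpha2_avg_effect_diff": dec.alpha_B2 - dec.alpha_b2,
        "alpha2_closed_form": L.a2 + (L.q1 - L.p1) * L.d,
    }
    ok = (
        abs(report["alpha1_substitution"] - report["alpha1_closed_form"]) <= atol
        and abs(report["alpha1_avg_effect_diff"] - report["alpha1_closed_form"]) <= atol
        and abs(report["alpha2_substitution"] - report["alpha2_closed_form"]) <= atol
        and abs(report["alpha2_avg_effect_diff"] - report["alpha2_closed_form"]) <= atol
    )
    return ok, report


def dominance_deviation_by_subtraction(L: LocusSpec) -> dict[str, float]:
    """Dominance deviations as remainders: G - E(G) - gA1 - gA2 per class.

    This is the independent route to the closed-form table
    {-2 q1 q2 d, 2 q1 p2 d, 2 p1 q2 d, -2 p1 p2 d}; the two must agree to
    machine precision, which is the module's core self-check.
    """
    dec = decompose_locus(L)
    G = dict(zip(CLASSES, L.genotypic_values()))
    a1 = {"B1B2": dec.gA1["B1"], "B1b2": dec.gA1["B1"],
          "b1B2": dec.gA1["b1"], "b1b2": dec.gA1["b1"]}
    a2 = {"B1B2": dec.gA2["B2"], "B1b2": dec.gA2["b2"],
          "b1B2": dec.gA2["B2"], "b1b2": dec.gA2["b2"]}
    return {c: G[c] - dec.mean - a1[c] - a2[c] for c in CLASSES}


def two_locus_epistatic_enumeration(
    Lk: LocusSpec, Lm: LocusSpec,
    aa_within1: float = 0.0, aa_within2: float = 0.0, aa_across: float = 0.0,
) -> dict[str, float]:
    """Exhaustive two-locus enumeration with additive-by-additive epistasis.

    The two loci are in linkage equilibrium, so all 16 two-locus hybrid
    genotype combinations carry product frequencies.  Epistatic codes are
    Kronecker products of the single-locus centered codes:

    * within group 1:  z1(k) * z1(m) with effect ``aa_within1``
    * within group 2:  z2(k) * z2(m) with effect ``aa_within2``
    * across groups:   z1(k) * z2(m) with effect ``aa_across``

    Returns the enumerated variances of every component, the closed-form
    epistatic variances (e.g. within-1: p1k q1k p1m q1m aa^2), the total, and
    the largest absolute weighted mean and pairwise covariance across all
    component codes (both zero under orthogonality).
    """
    # gamete states: 1 carries allele B, 0 carries b, per group and locus
    states = [(g1k, g2k, g1m, g2m)
              for g1k in (1, 0) for g2k in (1, 0)
              for g1m in (1, 0) for g2m in (1, 0)]
    f = np.array([
        (Lk.p1 if g1k else Lk.q1) * (Lk.p2 if g2k else Lk.q2)
        * (Lm.p1 if g1m else Lm.q1) * (Lm.p2 if g2m else Lm.q2)
        for g1k, g2k, g1m, g2m in states
    ])

    def z(p, carries_B):
        return (1.0 - p) if carries_B else -p

    dk = decompose_locus(Lk)
    dm = decompose_locus(Lm)
    z1k = np.array([z(Lk.p1, s[0]) for s in states])
    z2k = np.array([z(Lk.p2, s[1]) for s in states])
    z1m = np.array([z(Lm.p1, s[2]) for s in states])
    z2m = np.array([z(Lm.p2, s[3]) for s in states])
    wk = -2.0 * z1k * z2k
    wm = -2.0 * z1m * z2m

    codes = {
        "gA1_k": z1k * dk.alpha1, "gA2_k": z2k * dk.alpha2, "gD_k": wk * Lk.d,
        "gA1_m": z1m * dm.alpha1, "gA2_m": z2m * dm.alpha2, "gD_m": wm * Lm.d,
        "gAA11": z1k * z1m * aa_within1,
        "gAA22": z2k * z2m * aa_within2,
        "gAA12": z1k * z2m * aa_across,
    }

    def wvar(x):
        return float(f @ x**2) - float(f @ x) ** 2

    variances = {name: wvar(x) for name, x in codes.items()}
    total_code = sum(codes.values())
    raw_codes = {  # effect-free incidence codes, for the orthogonality report
        "z1k": z1k, "z2k": z2k, "wk": wk, "z1m": z1m, "z2m": z2m, "wm": wm,
        "z1k*z1m": z1k * z1m, "z2k*z2m": z2k * z2m, "z1k*z2m": z1k * z2m,
    }
    max_mean = max(abs(float(f @ x)) for x in raw_codes.values())
    max_cov = 0.0
    names = list(raw_codes)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            xa, xb = raw_codes[a], raw_codes[b]
            cov = float(f @ (xa * xb)) - float(f @ xa) * float(f @ xb)
            max_cov = max(max_cov, abs(cov))

    return {
        **{f"var_{k}": v for k, v in variances.items()},
        "var_total": wvar(total_code),
        "var_sum_components": float(sum(variances.values())),
        "closed_form_var_gAA11": Lk.p1 * Lk.q1 * Lm.p1 * Lm.q1 * aa_within1**2,
        "closed_form_var_gAA22": Lk.p2 * Lk.q2 * Lm.p2 * Lm.q2 * aa_within2**2,
        "closed_form_var_gAA12": Lk.p1 * Lk.q1 * Lm.p2 * Lm.q2 * aa_across**2,
        "max_abs_weighted_mean": max_mean,
        "max_abs_weighted_cov": max_cov,
    }


def genotypic_variance_partition(components: dict[str, float]) -> dict[str, float]:
    """Total genotypic variance and GCA/SCA aggregates from component variances.

    Recognized keys: A1, A2, D, AA11, AA22, AA12, A1D, A2D, DD, r1, r2
    (missing keys count as zero).  Aggregates::

        GCA1 = A1 + AA11 + r1        GCA2 = A2 + AA22 + r2
        SCA  = D + AA12 + A1D + A2D + DD
        G    = GCA1 + GCA2 + SCA     (ignoring third and higher order terms)

    The "residual genetic" r variances absorb unmodeled higher-order
    within-group epistasis and therefore belong to their group's GCA.
    """
    known = {"A1", "A2", "D", "AA11", "AA22", "AA12", "A1D", "A2D", "DD", "r1", "r2"}
    unknown = set(components) - known
    if unknown:
        raise KeyError(f"unknown variance components: {sorted(unknown)}")
    neg = {k: v for k, v in components.items() if v < 0}
    if neg:
        raise ValueError(f"negative variance components: {neg}")
    c = {k: components.get(k, 0.0) for k in known}
    gca1 = c["A1"] + c["AA11"] + c["r1"]
    gca2 = c["A2"] + c["AA22"] + c["r2"]
    sca = c["D"] + c["AA12"] + c["A1D"] + c["A2D"] + c["DD"]
    return {
        "GCA1": gca1, "GCA2": gca2, "SCA": sca,
        "total": gca1 + gca2 + sca,
    }
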