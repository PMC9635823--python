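"""Analytic pedigree kinship, autosomal and X-chromosomal, with hypothesis ranking.

The autosomal kinship coefficient phi(a, b) is the probability that one
allele drawn from each individual is identical by descent; it follows the
classical recursion phi(a, b) = (phi(father_a, b) + phi(mother_a, b)) / 2
on a non-ancestor of b, with phi(a, a) = (1 + f_a) / 2 and unrelated
founders.  The X-chromosomal version accounts for male hemizygosity: a male
transmits his single X to daughters only, so for male a,
phiX(a, b) = phiX(mother_a, b) and phiX(a, a) = 1 (drawing "both" alleles
from a hemizygous male always gives the same allele).  Under this convention
mother-son and father-daughter both give theta_X = 0.5 and father-son 0.

Because paternal and maternal variants of the same autosomal degree differ
on the X, an observed (theta_auto, theta_X) pair discriminates pedigree
hypotheses: the module enumerates all sex-resolved first- to third-degree
relationships (third degree: great-grandparents, great-aunts/uncles,
half-aunts/uncles and first cousins), scores each against the observation,
and checks the recursions against a gene-dropping Monte-Carlo oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

FEMALE, MALE = "F", "M"


@dataclass
class Pedigree:
    """Sexed directed-ancestry graph: members as (sex, father, mother)."""

    members: dict[str, tuple[str, str | None, str | None]] = field(default_factory=dict)

    def add(self, member_id: str, sex: str, father: str | None = None,
            mother: str | None = None) -> str:
        if sex not in (FEMALE, MALE):
            raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
        if (father is None) != (mother is None):
            raise ValueError(f"{member_id}: specify both parents or neither")
        self.members[member_id] = (sex, father, mother)
        return member_id

    def sex(self, member_id: str) -> str:
        return self.members[member_id][0]

    def parents(self, member_id: str) -> tuple[str | None, str | None]:
        return self.members[member_id][1:]

    def validate(self) -> None:
        for mid, (sex, father, mother) in self.members.items():
            for parent, want in ((father, MALE), (mother, FEMALE)):
                if parent is None:
                    continue
                if parent not in self.members:
                    raise ValueError(f"{mid}: unknown parent {parent}")
                if self.members[parent][0] != want:
                    raise ValueError(f"{mid}: parent {parent} has inconsistent sex")
        self.topological_order()  # raises on cycles

    def topological_order(self) -> list[str]:
        depth = self.depths()
        return sorted(self.members, key=lambda m: (depth[m], m))

    def depths(self) -> dict[str, int]:
        """Generation depth: founders 0, child = 1 + max(parent depths)."""
        depth: dict[str, int] = {}

        def rec(m: str, trail: frozenset) -> int:
            if m in trail:
                raise ValueError(f"pedigree cycle through {m}")
            if m in depth:
                return depth[m]
            father, mother = self.parents(m)
            if father is None:
                depth[m] = 0
            else:
                depth[m] = 1 + max(rec(father, trail | {m}), rec(mother, trail | {m}))
            return depth[m]

        for m in self.members:
            rec(m, frozenset())
        return depth


def kinship_auto(ped: Pedigree, a: str, b: str) -> float:
    """Autosomal kinship coefficient phi(a, b) by recursion."""
    for m in (a, b):
        if m not in ped.members:
            raise KeyError(f"{m} not in pedigree")
    depth = ped.depths()
    cache: dict[tuple[str, str], float] = {}

    def phi(x: str, y: str) -> float:
        if depth[x] < depth[y] or (depth[x] == depth[y] and x > y):
            x, y = y, x
        key = (x, y)
        if key in cache:
            return cache[key]
        fx, mx = ped.parents(x)
        if x == y:
            val = 0.5 * (1.0 + (phi(fx, mx) if fx else 0.0))
        elif fx is None:
            # x is a founder at max depth among the two => unrelated unless equal
            val = 0.0 if ped.parents(y)[0] is None else phi_asym(y, x)
        else:
            val = 0.5 * (phi(fx, y) + phi(mx, y))
        cache[key] = val
        return val

    def phi_asym(x: str, y: str) -> float:
        fx, mx = ped.parents(x)
        if fx is None:
            return 0.0
        return 0.5 * (phi(fx, y) + phi(mx, y))

    return phi(a, b)


def kinship_x(ped: Pedigree, a: str, b: str) -> float:
    """X-chromosomal kinship coefficient with male hemizygosity."""
    for m in (a, b):
        if m not in ped.members:
            raise KeyError(f"{m} not in pedigree")
    depth = ped.depths()
    cache: dict[tuple[str, str], float] = {}

    def phi(x: str, y: str) -> float:
        if depth[x] < depth[y] or (depth[x] == depth[y] and x > y):
            x, y = y, x
        key = (x, y)
        if key in cache:
            return cache[key]
        fx, mx = ped.parents(x)
        if x == y:
            if ped.sex(x) == MALE:
                val = 1.0
            else:
                fx_inb = phi(fx, mx) if fx else 0.0
                val = 0.5 * (1.0 + fx_inb)
        elif fx is None:
            other_f = ped.parents(y)[0]
            val = 0.0 if other_f is None else phi_asym(y, x)
        elif ped.sex(x) == MALE:
            val = phi(mx, y)
        else:
            val = 0.5 * (phi(fx, y) + phi(mx, y))
        cache[key] = val
        return val

    def phi_asym(x: str, y: str) -> float:
        fx, mx = ped.parents(x)
        if fx is None:
            return 0.0
        if ped.sex(x) == MALE:
            return phi(mx, y)
        return 0.5 * (phi(fx, y) + phi(mx, y))

    return phi(a, b)


# ---------------------------------------------------------------------------
# hypothesis enumeration
# ---------------------------------------------------------------------------

@dataclass
class RelationHypothesis:
    name: str
    pedigree: Pedigree
    pair: tuple[str, str]  # (proband, relative)
    degree: int
    theta_auto: float
    theta_x: float
    score: float | None = None


def _founder_pair(ped: Pedigree, tag: str) -> tuple[str, str]:
    return (ped.add(f"{tag}_f", MALE), ped.add(f"{tag}_m", FEMALE))


def _hypothesis(name: str, degree: int, build) -> RelationHypothesis:
    """Build a pedigree via ``build(ped) -> (proband, relative)`` and score it."""
    ped = Pedigree()
    proband, relative = build(ped)
    ped.validate()
    return RelationHypothesis(
        name=name,
        pedigree=ped,
        pair=(proband, relative),
        degree=degree,
        theta_auto=kinship_auto(ped, proband, relative),
        theta_x=kinship_x(ped, proband, relative),
    )


_LINE = {MALE: "father", FEMALE: "mother"}
_GP = {(MALE, MALE): "father's father", (MALE, FEMALE): "father's mother",
       (FEMALE, MALE): "mother's father", (FEMALE, FEMALE): "mother's mother"}


def enumerate_hypotheses(
    proband_sex: str,
    relative_sex: str,
    degree: int,
    proband_non_ancestral: bool = True,
) -> list[RelationHypothesis]:
    """All sex-resolved pedigree hypotheses for a pair at a given degree.

    The proband is the first member of the pair (e.g. a child who died before
    fertile age); with ``proband_non_ancestral`` every hypothesis placing the
    proband upstream of the relative is pruned.  Degree 3 covers exactly the
    great-grandparent, great-aunt/uncle, half-aunt/uncle and first-cousin
    classes, each in all paternal/maternal lineage variants.
    """
    if degree not in (1, 2, 3):
        raise ValueError("supported degrees: 1, 2, 3")
    ps, rs = proband_sex, relative_sex
    hyps: list[RelationHypothesis] = []

    def rel_word(female: str, male: str) -> str:
        return female if rs == FEMALE else male

    if degree == 1:
        def parent(ped):
            gf, gm = _founder_pair(ped, "g")
            rel = gf if rs == MALE else gm
            pro = ped.add("proband", ps, gf, gm)
            return pro, rel

        hyps.append(_hypothesis(rel_word("mother", "father"), 1, parent))
        if not proband_non_ancestral:
            def child(ped):
                sf, sm = _founder_pair(ped, "s")
                pro = sf if ps == MALE else sm
                rel = ped.add("relative", rs, sf, sm)
                return pro, rel
            hyps.append(_hypothesis(rel_word("daughter", "son"), 1, child))

        def full_sib(ped):
            f, m = _founder_pair(ped, "g")
            pro = ped.add("proband", ps, f, m)
            rel = ped.add("relative", rs, f, m)
            return pro, rel

        hyps.append(_hypothesis(rel_word("full sister", "full brother"), 1, full_sib))

    elif degree == 2:
        for shared_sex in (MALE, FEMALE):
            def half_sib(ped, shared_sex=shared_sex):
                if shared_sex == MALE:
                    sh = ped.add("shared_f", MALE)
                    w1 = ped.add("w1", FEMALE)
                    w2 = ped.add("w2", FEMALE)
                    pro = ped.add("proband", ps, sh, w1)
                    rel = ped.add("relative", rs, sh, w2)
                else:
                    sh = ped.add("shared_m", FEMALE)
                    h1 = ped.add("h1", MALE)
                    h2 = ped.add("h2", MALE)
                    pro = ped.add("proband", ps, h1, sh)
                    rel = ped.add("relative", rs, h2, sh)
                return pro, rel

            side = "paternal" if shared_sex == MALE else "maternal"
            hyps.append(_hypothesis(
                f"{side} {rel_word('half sister', 'half brother')}", 2, half_sib))
        for via in (MALE, FEMALE):
            def grandparent(ped, via=via):
                # relative is the proband's grandparent through `via` parent
                if rs == MALE:
                    gpa = ped.add("relative", MALE)
                    gma = ped.add("spouse", FEMALE)
                else:
                    gpa = ped.add("spouse", MALE)
                    gma = ped.add("relative", FEMALE)
                link = ped.add("link", via, gpa, gma)
                other = ped.add("other", FEMALE if via == MALE else MALE)
                father = link if via == MALE else other
                mother = other if via == MALE else link
                pro = ped.add("proband", ps, father, mother)
                return pro, "relative"

            hyps.append(_hypothesis(
                f"{_LINE[via]}'s {rel_word('mother (grandmother)', 'father (grandfather)')}",
                2, grandparent))
            if not proband_non_ancestral:
                def grandchild(ped, via=via):
                    pro_sp = ped.add("pro_spouse", FEMALE if ps == MALE else MALE)
                    pro = ped.add("proband", ps)
                    father = pro if ps == MALE else pro_sp
                    mother = pro_sp if ps == MALE else pro
                    link = ped.add("link", via, father, mother)
                    link_sp = ped.add("link_spouse", FEMALE if via == MALE else MALE)
                    lf = link if via == MALE else link_sp
                    lm = link_sp if via == MALE else link
                    rel = ped.add("relative", rs, lf, lm)
                    return "proband", rel
                hyps.append(_hypothesis(
                    f"{'son' if via == MALE else 'daughter'}'s "
                    f"{rel_word('daughter (granddaughter)', 'son (grandson)')}",
                    2, grandchild))
        for via in (MALE, FEMALE):
            def avuncular(ped, via=via):
                # relative is a full sibling of the proband's `via` parent
                gf, gm = _founder_pair(ped, "g")
                link = ped.add("link", via, gf, gm)
                rel = ped.add("relative", rs, gf, gm)
                other = ped.add("other", FEMALE if via == MALE else MALE)
                father = link if via == MALE else other
                mother = other if via == MALE else link
                pro = ped.add("proband", ps, father, mother)
                return pro, rel

            hyps.append(_hypothesis(
                f"{_LINE[via]}'s {rel_word('sister (aunt)', 'brother (uncle)')}",
                2, avuncular))
        for sib_sex in (MALE, FEMALE):
            def sibs_child(ped, sib_sex=sib_sex):
                # relative is the child of the proband's full sibling
                gf, gm = _founder_pair(ped, "g")
                pro = ped.add("proband", ps, gf, gm)
                sib = ped.add("sib", sib_sex, gf, gm)
                sp = ped.add("sib_spouse", FEMALE if sib_sex == MALE else MALE)
                father = sib if sib_sex == MALE else sp
                mother = sp if sib_sex == MALE else sib
                rel = ped.add("relative", rs, father, mother)
                return pro, rel

            hyps.append(_hypothesis(
                f"{'brother' if sib_sex == MALE else 'sister'}'s child "
                f"({rel_word('niece', 'nephew')})", 2, sibs_child))

    else:  # degree 3
        for via1, via2 in itertools.product((MALE, FEMALE), repeat=2):
            gp_name = _GP[(via1, via2)]

            def great_grandparent(ped, via1=via1, via2=via2):
                if rs == MALE:
                    ggf = ped.add("relative", MALE)
                    ggm = ped.add("gg_spouse", FEMALE)
                else:
                    ggf = ped.add("gg_spouse", MALE)
                    ggm = ped.add("relative", FEMALE)
                gp = ped.add("gp", via2, ggf, ggm)
                gp_sp = ped.add("gp_spouse", FEMALE if via2 == MALE else MALE)
                pf = gp if via2 == MALE else gp_sp
                pm = gp_sp if via2 == MALE else gp
                parent = ped.add("parent", via1, pf, pm)
                other = ped.add("other", FEMALE if via1 == MALE else MALE)
                father = parent if via1 == MALE else other
                mother = other if via1 == MALE else parent
                pro = ped.add("proband", ps, father, mother)
                return pro, "relative"

            hyps.append(_hypothesis(
                f"{gp_name}'s {rel_word('mother (great-grandmother)', 'father (great-grandfather)')}",
                3, great_grandparent))

            def great_auncle(ped, via1=via1, via2=via2):
                # relative is a full sibling of the (via1, via2) grandparent
                ggf, ggm = _founder_pair(ped, "gg")
                gp = ped.add("gp", via2, ggf, ggm)
                rel = ped.add("relative", rs, ggf, ggm)
                gp_sp = ped.add("gp_spouse", FEMALE if via2 == MALE else MALE)
                pf = gp if via2 == MALE else gp_sp
                pm = gp_sp if via2 == MALE else gp
                parent = ped.add("parent", via1, pf, pm)
                other = ped.add("other", FEMALE if via1 == MALE else MALE)
                father = parent if via1 == MALE else other
                mother = other if via1 == MALE else parent
                pro = ped.add("proband", ps, father, mother)
                return pro, rel

            hyps.append(_hypothesis(
                f"{gp_name}'s {rel_word('sister (great-aunt)', 'brother (great-uncle)')}",
                3, great_auncle))

            def half_auncle(ped, via1=via1, via2=via2):
                # relative is the half-sibling of the `via1` parent, shared
                # grandparent of sex `via2`
                if via2 == MALE:
                    sh = ped.add("shared_gf", MALE)
                    w1 = ped.add("w1", FEMALE)
                    w2 = ped.add("w2", FEMALE)
                    parent = ped.add("parent", via1, sh, w1)
                    rel = ped.add("relative", rs, sh, w2)
                else:
                    sh = ped.add("shared_gm", FEMALE)
                    h1 = ped.add("h1", MALE)
                    h2 = ped.add("h2", MALE)
                    parent = ped.add("parent", via1, h1, sh)
                    rel = ped.add("relative", rs, h2, sh)
                other = ped.add("other", FEMALE if via1 == MALE else MALE)
                father = parent if via1 == MALE else other
                mother = other if via1 == MALE else parent
                pro = ped.add("proband", ps, father, mother)
                return pro, rel

            shared = "grandfather" if via2 == MALE else "grandmother"
            hyps.append(_hypothesis(
                f"{_LINE[via1]}'s {rel_word('half sister (half-aunt)', 'half brother (half-uncle)')} "
                f"via shared {shared}", 3, half_auncle))

            def first_cousin(ped, via1=via1, via2=via2):
                # relative is the child of the `via1` parent's full sibling of
                # sex `via2`
                gf, gm = _founder_pair(ped, "g")
                parent = ped.add("parent", via1, gf, gm)
                sib = ped.add("sib", via2, gf, gm)
                sib_sp = ped.add("sib_spouse", FEMALE if via2 == MALE else MALE)
                sf = sib if via2 == MALE else sib_sp
                sm = sib_sp if via2 == MALE else sib
                rel = ped.add("relative", rs, sf, sm)
                other = ped.add("other", FEMALE if via1 == MALE else MALE)
                father = parent if via1 == MALE else other
                mother = other if via1 == MALE else parent
                pro = ped.add("proband", ps, father, mother)
                return pro, rel

            sib_word = "brother" if via2 == MALE else "sister"
            hyps.append(_hypothesis(
                f"{_LINE[via1]}'s {sib_word}'s child (first cousin)", 3, first_cousin))

    return hyps


def rank_hypotheses(
    hypotheses: list[RelationHypothesis],
    theta_auto: float,
    se_auto: float,
    theta_x: float,
    se_x: float,
) -> list[RelationHypothesis]:
    """Rank hypotheses by squared standardized distance to the observation.

    score = ((theta_auto_exp - obs)/se_auto)^2 + ((theta_X_exp - obs)/se_x)^2,
    ascending; ties broken by name for determinism.
    """
    if se_auto <= 0 or se_x <= 0:
        raise ValueError("standard errors must be positive")
    scored = []
    for h in hypotheses:
        score = (
            ((h.theta_auto - theta_auto) / se_auto) ** 2
            + ((h.theta_x - theta_x) / se_x) ** 2
        )
        scored.append(RelationHypothesis(h.name, h.pedigree, h.pair, h.degree,
                                         h.theta_auto, h.theta_x, float(score)))
    return sorted(scored, key=lambda h: (h.score, h.name))


# ---------------------------------------------------------------------------
# gene-dropping Monte-Carlo oracle
# ---------------------------------------------------------------------------

def gene_drop_oracle(
    ped: Pedigree,
    pair: tuple[str, str],
    n_reps: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Empirical theta_auto and theta_X by repeated unlinked transmission.

    Founders receive unique allele labels; each replicate transmits alleles
    down the pedigree (one uniform pick per parent for autosomes; X follows
    hemizygous rules).  theta is the probability that one allele drawn from
    each individual is identical by descent, averaged exactly over the
    within-replicate draw combinations; Monte-Carlo SEs accompany.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    order = ped.topological_order()
    a, b = pair

    # autosomal: each member holds (n_reps, 2) allele labels
    alleles: dict[str, np.ndarray] = {}
    counter = itertools.count()
    for m in order:
        father, mother = ped.parents(m)
        if father is None:
            lab = np.array([next(counter), next(counter)])
            alleles[m] = np.broadcast_to(lab, (n_reps, 2)).copy()
        else:
            pick_f = rng.integers(2, size=n_reps)
            pick_m = rng.integers(2, size=n_reps)
            alleles[m] = np.stack(
                [alleles[father][np.arange(n_reps), pick_f],
                 alleles[mother][np.arange(n_reps), pick_m]], axis=1
            )
    ibd = (alleles[a][:, :, None] == alleles[b][:, None, :]).mean(axis=(1, 2))
    theta_auto = float(ibd.mean())
    se_auto = float(ibd.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else np.nan

    # X: females (n_reps, 2), males (n_reps, 1) from the mother only
    xall: dict[str, np.ndarray] = {}
    counter = itertools.count()
    for m in order:
        father, mother = ped.parents(m)
        sex = ped.sex(m)
        if father is None:
            if sex == MALE:
                xall[m] = np.full((n_reps, 1), next(counter))
            else:
                lab = np.array([next(counter), next(counter)])
                xall[m] = np.broadcast_to(lab, (n_reps, 2)).copy()
        else:
            k = xall[mother].shape[1]
            pick = rng.integers(k, size=n_reps)
            from_mother = xall[mother][np.arange(n_reps), pick][:, None]
            if sex == MALE:
                xall[m] = from_mother
            else:
                from_father = xall[father][:, :1]  # single X (males) or... see below
                if xall[father].shape[1] == 2:
                    raise AssertionError("father with diploid X")
                xall[m] = np.concatenate([from_father, from_mother], axis=1)
    ibd_x = (xall[a][:, :, None] == xall[b][:, None, :]).mean(axis=(1, 2))
    theta_x = float(ibd_x.mean())
    se_x = float(ibd_x.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else np.nan

    return {
        "theta_auto": theta_auto,
        "se_auto": se_auto,
        "theta_x": theta_x,
        "se_x": se_x,
        "n_reps": n_reps,
    }
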