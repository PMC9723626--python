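"""rrn core-gene-environment nomenclature.

Each rrn locus is described by its core-gene environment: the nearest core
gene plus that gene's previous and next core genes along the chromosome.
The six most frequent environments in a panel receive the canonical letters
A through F (ordered by the consensus rank of their nearest core genes);
other environments sharing a core gene with one canonical environment get
that letter in lower case with a number (e.g. ``e2``), those sharing genes
with two canonical environments get a hybrid bracket label (``[d/e]``), and
environments sharing none get fresh lower-case letters from ``g`` onward.

An environment read against the consensus order in increasing rank order is
"sense"; read in decreasing order it is "antisense" and its label carries an
asterisk.  A genome's configuration lists the labels in chromosomal order
together with the orientation of dnaA; a configuration and its reverse
complement (labels reversed, asterisks toggled, dnaA sign flipped) are
equivalent, and ``canonicalize`` returns the lexicographically smaller of
the two forms, so e.g. ``rrn F*E*D*C*B*A* dnaA-`` reduces to
``rrn ABCDEF dnaA+``.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .genome_model import GenomeAnnotation, RrnLocus
from .skeleton import CoreOrder

logger = logging.getLogger(__name__)

#: suffix rendered for a triplet whose consensus ranks are non-monotone
BROKEN_MARK = "~"


@dataclass(frozen=True)
class RrnEnvironment:
    locus_id: str
    nearest_core: str
    prev_core: Optional[str]
    next_core: Optional[str]
    orientation: str  # sense | antisense | broken
    locus_start: int = 0

    @property
    def key(self) -> frozenset:
        """Environment identity: the unordered triplet of core group ids."""
        return frozenset(
            g for g in (self.prev_core, self.nearest_core, self.next_core) if g
        )


def _span_gap(a_start, a_end, b_start, b_end) -> int:
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0  # overlapping spans


def environment_of(
    locus: RrnLocus,
    genome: GenomeAnnotation,
    core_group_ids: Iterable[str],
    consensus: CoreOrder,
) -> RrnEnvironment:
    """Core-gene environment of one rrn locus.

    The nearest core gene minimizes the span-to-span distance to the locus
    (zero when overlapping; ties break to the lower consensus rank).  The
    previous/next core genes are its chromosomal neighbors.  Orientation is
    sense when the triplet's consensus ranks strictly increase along the
    chromosome, antisense when they strictly decrease, and broken otherwise.
    """
    rank = consensus.rank_of
    core = [g for g in genome.core_genes(core_group_ids) if g.orthogroup_id in rank]
    core.sort(key=lambda g: g.start)
    if len(core) < 3:
        raise ValueError(f"{genome.genome_id}: fewer than 3 ranked core genes")
    best_i = None
    best = None
    for i, g in enumerate(core):
        d = _span_gap(locus.span[0], locus.span[1], g.start, g.end)
        k = (d, rank[g.orthogroup_id])
        if best is None or k < best:
            best, best_i = k, i
    if best_i is not None and best is not None:
        ties = [
            i
            for i, g in enumerate(core)
            if _span_gap(locus.span[0], locus.span[1], g.start, g.end) == best[0]
        ]
        if len(ties) > 1:
            logger.debug(
                "%s %s: nearest-core tie broken to lower rank",
                genome.genome_id,
                locus.locus_id,
            )
    nearest = core[best_i]
    prev = core[best_i - 1] if best_i > 0 else None
    nxt = core[best_i + 1] if best_i < len(core) - 1 else None
    ranks = [rank[g.orthogroup_id] for g in (prev, nearest, nxt) if g is not None]
    if all(a < b for a, b in zip(ranks, ranks[1:])):
        orientation = "sense"
    elif all(a > b for a, b in zip(ranks, ranks[1:])):
        orientation = "antisense"
    else:
        orientation = "broken"
    return RrnEnvironment(
        locus_id=locus.locus_id,
        nearest_core=nearest.orthogroup_id,
        prev_core=prev.orthogroup_id if prev else None,
        next_core=nxt.orthogroup_id if nxt else None,
        orientation=orientation,
        locus_start=locus.span[0],
    )


def environments_of_genome(genome, core_group_ids, consensus) -> list:
    return [
        environment_of(loc, genome, core_group_ids, consensus)
        for loc in sorted(genome.rrn_loci, key=lambda l: l.span[0])
    ]


class EnvironmentDictionary:
    """Panel-wide mapping from environment key to nomenclature label."""

    CANONICAL = "ABCDEF"

    def __init__(self, labels: Mapping[frozenset, str], canonical_keys: Mapping[str, frozenset]):
        self.labels = dict(labels)
        self.canonical_keys = dict(canonical_keys)

    def label_for(self, env: RrnEnvironment) -> str:
        return self.labels[env.key]

    def to_json(self) -> str:
        return json.dumps(
            [
                {"environment": sorted(k), "label": v}
                for k, v in sorted(self.labels.items(), key=lambda kv: kv[1])
            ],
            indent=1,
        )


def build_environment_dictionary(
    panel_environments: Mapping[str, list],
    consensus: CoreOrder,
) -> EnvironmentDictionary:
    """Assign nomenclature labels from panel-wide environment frequencies.

    ``panel_environments`` maps genome_id to that genome's environments in
    chromosomal order.  The six most frequent environment keys become the
    canonical letters A..F in consensus-rank order of their nearest core
    genes; remaining keys are labeled in genome-id-sorted discovery order by
    the sharing rules described in the module docstring.
    """
    rank = consensus.rank_of
    freq: Counter = Counter()
    min_rank: dict = {}
    for envs in panel_environments.values():
        for env in envs:
            freq[env.key] += 1
            r = rank.get(env.nearest_core, len(rank) + 1)
            min_rank[env.key] = min(min_rank.get(env.key, r), r)
    ordered = sorted(freq, key=lambda k: (-freq[k], min_rank[k], sorted(k)))
    top = ordered[:6]
    if len(top) < 6:
        warnings.warn(
            f"only {len(top)} distinct rrn environments in panel; "
            "assigning canonical letters to what exists",
            stacklevel=2,
        )
    top.sort(key=lambda k: min_rank[k])
    labels: dict = {}
    canonical_keys: dict = {}
    for letter, key in zip(EnvironmentDictionary.CANONICAL, top):
        labels[key] = letter
        canonical_keys[letter] = key
    variant_counter: Counter = Counter()
    novel_keys: dict = {}  # letter -> list of keys
    next_novel = ord("g")
    for genome_id in sorted(panel_environments):
        for env in sorted(panel_environments[genome_id], key=lambda e: e.locus_start):
            key = env.key
            if key in labels:
                continue
            sharing = [
                letter
                for letter in canonical_keys
                if key & canonical_keys[letter]
            ]
            sharing.sort()
            if len(sharing) == 1:
                letter = sharing[0].lower()
                variant_counter[letter] += 1
                labels[key] = f"{letter}{variant_counter[letter] + 1}"
            elif len(sharing) >= 2:
                labels[key] = "[" + "/".join(s.lower() for s in sharing[:2]) + "]"
            else:
                shared_novel = None
                for letter, keys in novel_keys.items():
                    if any(key & k for k in keys):
                        shared_novel = letter
                        break
                if shared_novel is None:
                    shared_novel = chr(next_novel)
                    next_novel += 1
                    novel_keys[shared_novel] = []
                novel_keys[shared_novel].append(key)
                labels[key] = f"{shared_novel}{len(novel_keys[shared_novel])}"
    return EnvironmentDictionary(labels, canonical_keys)


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Configuration:
    """Per-genome rrn label string (chromosomal order) with dnaA sign."""

    genome_id: str
    tokens: tuple  # labels with "*" (antisense) or "~" (broken) suffix
    dnaA_sign: str

    def to_string(self) -> str:
        return f"rrn {''.join(self.tokens)} dnaA{self.dnaA_sign}"

    @property
    def canonical_form(self) -> str:
        return canonicalize(self).to_string()


def _toggle(token: str) -> str:
    if token.endswith(BROKEN_MARK):
        return token
    if token.endswith("*"):
        return token[:-1]
    return token + "*"


def classify_configuration(
    genome: GenomeAnnotation,
    dictionary: EnvironmentDictionary,
    core_group_ids,
    consensus: CoreOrder,
) -> Configuration:
    """Label every rrn locus and read off the configuration string.

    Labels are listed in chromosomal order; antisense environments carry an
    asterisk, non-monotone (broken) ones a tilde.  The dnaA sign is the
    strand of dnaA in the genome's given orientation; :func:`canonicalize`
    maps the string onto its reverse-complement-equivalent normal form.
    """
    if len(genome.rrn_loci) < 6:
        warnings.warn(
            f"{genome.genome_id}: {len(genome.rrn_loci)} rrn loci "
            "(fewer than the canonical six); compartment-level statistics "
            "may be affected",
            stacklevel=2,
        )
    envs = environments_of_genome(genome, core_group_ids, consensus)
    tokens = []
    for env in envs:
        label = dictionary.label_for(env)
        if env.orientation == "antisense":
            label += "*"
        elif env.orientation == "broken":
            label += BROKEN_MARK
        tokens.append(label)
    return Configuration(
        genome_id=genome.genome_id,
        tokens=tuple(tokens),
        dnaA_sign="+" if genome.dnaA.strand == "+" else "-",
    )


def canonicalize(config: Configuration) -> Configuration:
    """Normal form under reverse-complement equivalence (idempotent).

    The reversed form reverses the label order, toggles every asterisk and
    flips the dnaA sign; the lexicographically smaller of the two token
    sequences (sign as tiebreak) is returned.
    """
    reversed_tokens = tuple(_toggle(t) for t in reversed(config.tokens))
    reversed_sign = "-" if config.dnaA_sign == "+" else "+"
    fwd = (config.tokens, config.dnaA_sign)
    rev = (reversed_tokens, reversed_sign)
    tokens, sign = min(fwd, rev)
    return Configuration(config.genome_id, tokens, sign)


def equivalent(c1: Configuration, c2: Configuration) -> bool:
    a, b = canonicalize(c1), canonicalize(c2)
    return a.tokens == b.tokens and a.dnaA_sign == b.dnaA_sign
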