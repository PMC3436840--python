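"""Synthetic pharmacogenomic world generator.

Emulates the statistical structure the prediction method relies on --
similar drugs hit similar proteins, and drugs sharing targets share
side-effect spectra -- at desk scale, so that every pipeline stage can be
tested end to end without any external database:

* drugs come in classes; each class has a signature set of side-effect
  keywords; adverse-event reports name one primary-suspect (PS) drug (with
  occasional SS/C/I co-medications to exercise the role filter) and draw
  keywords from the class signature plus a heavy-tailed background pool;
* chemical fingerprints share a common bit block across all drugs and a
  class-specific block, placing within-class Tanimoto in a high band and
  between-class in a low band;
* protein targets come in families; each family member is a mutated copy
  of a family ancestor sequence;
* the gold standard links each drug class to its assigned target family
  with probability ``class_target_fidelity`` (off-block links appear with
  the complementary probability, so fidelity 1 gives an exactly
  block-structured interaction matrix).

The background keyword pool follows a truncated power law so that, under
the generator's scaled filter thresholds, both vocabulary filter branches
fire: the most popular keywords are removed as too frequent and the long
tail as too rare.  Everything is fully determined by the seed, and the
generated truth is retained so parsers and profilers can be checked
exactly against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from pharmlink.aers import DrugEntry, Report, ReportSet, write_quarter

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class WorldSpec:
    """Parameters of the synthetic world; fully determined by ``seed``."""

    n_drug_classes: int = 5
    drugs_per_class: int = 8
    n_target_families: int = 4
    targets_per_family: int = 5
    n_keywords: int = 2000
    reports_per_drug: int = 50
    keyword_frequency_tail: float = 1.5  # power-law exponent of background pool
    class_keyword_overlap: float = 0.8   # per-draw prob. of the shared common-event pool
    class_target_fidelity: float = 0.95
    signature_size: int = 40
    shared_pool_size: int = 200          # common adverse events shared by all classes
    private_keywords_per_drug: int = 12  # drug-idiosyncratic side effects
    private_keyword_rate: float = 0.15   # per-draw prob. of the drug's private set
    keywords_per_report: float = 5.0     # mean keywords per report
    background_rate: float = 0.3         # mean background keywords per report
    n_fingerprint_bits: int = 256
    chem_within_class: float = 0.80
    chem_between_class: float = 0.15
    seq_length: int = 300
    seq_mutation_rate: float = 0.05
    missing_drug_fraction: float = 0.0   # drugs withheld from the report roster
    n_quarters: int = 4
    max_freq: float = 0.05               # scaled vocabulary filters for this world
    min_reports: int = 5
    seed: int = 42

    def __post_init__(self) -> None:
        for name in (
            "n_drug_classes", "drugs_per_class", "n_target_families",
            "targets_per_family", "n_keywords", "reports_per_drug",
            "signature_size", "n_fingerprint_bits", "seq_length", "n_quarters",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "class_keyword_overlap", "class_target_fidelity",
            "private_keyword_rate", "seq_mutation_rate",
            "missing_drug_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.class_keyword_overlap + self.private_keyword_rate > 1.0:
            raise ValueError(
                "class_keyword_overlap + private_keyword_rate must not exceed 1"
            )
        if self.chem_between_class >= self.chem_within_class:
            raise ValueError(
                "infeasible fingerprint bands: chem_between_class must be "
                "below chem_within_class"
            )

    @property
    def n_drugs(self) -> int:
        return self.n_drug_classes * self.drugs_per_class

    @property
    def n_targets(self) -> int:
        return self.n_target_families * self.targets_per_family


@dataclass
class WorldTruth:
    """Ground truth retained for exact verification of the pipeline."""

    spec: WorldSpec
    drug_class: dict[str, int]
    target_family: dict[str, int]
    class_family: dict[int, int]
    interactions: list[tuple[str, str]]
    class_keywords: dict[int, list[str]]
    private_keywords: dict[str, list[str]]
    reports: ReportSet
    fingerprints: dict[str, list[int]] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)
    reported_drugs: list[str] = field(default_factory=list)

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.drug_class)

    @property
    def target_ids(self) -> list[str]:
        return sorted(self.target_family)

    def keyword_support(self, drug_id: str) -> set[str]:
        """Keywords co-reported with a drug (PS/SS roles) over all reports."""
        out: set[str] = set()
        for r in self.reports.reports:
            if any(
                e.drug_id == drug_id and e.role in ("PS", "SS") for e in r.drugs
            ):
                out |= r.keywords
        return out


def _power_law_weights(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks ** (-exponent)
    rng.shuffle(w)  # decouple keyword index from popularity rank
    return w / w.sum()


def generate_world(
    spec: WorldSpec, out_dir: str | Path | None = None
) -> WorldTruth:
    """Generate the synthetic world; optionally write all fixture files.

    When ``out_dir`` is given, writes DRUG/REAC quarterly files,
    fingerprint TSV, protein FASTA, the gold-standard edge list and a
    truth JSON.  Same seed => byte-identical files.
    """
    rng = np.random.default_rng(spec.seed)

    drug_ids = [f"D{i:04d}" for i in range(spec.n_drugs)]
    drug_class = {d: i // spec.drugs_per_class for i, d in enumerate(drug_ids)}
    target_ids = [f"T{j:04d}" for j in range(spec.n_targets)]
    target_family = {t: j // spec.targets_per_family for j, t in enumerate(target_ids)}
    class_family = {
        c: c % spec.n_target_families for c in range(spec.n_drug_classes)
    }

    keywords = [f"kw{k:05d}" for k in range(spec.n_keywords)]

    # keyword pools: a class-independent shared pool of common adverse
    # events, disjoint class signatures, and disjoint per-drug private sets
    n_fixed = (
        spec.shared_pool_size
        + spec.n_drug_classes * spec.signature_size
        + spec.n_drugs * spec.private_keywords_per_drug
    )
    if n_fixed > spec.n_keywords:
        raise ValueError("n_keywords too small for the configured pools")
    perm = rng.permutation(spec.n_keywords)
    shared_pool = perm[: spec.shared_pool_size]
    cursor = spec.shared_pool_size
    class_keywords: dict[int, list[str]] = {}
    for c in range(spec.n_drug_classes):
        idx = perm[cursor : cursor + spec.signature_size]
        class_keywords[c] = sorted(keywords[k] for k in idx)
        cursor += spec.signature_size
    private_keywords: dict[str, list[str]] = {}
    for d in drug_ids:
        idx = perm[cursor : cursor + spec.private_keywords_per_drug]
        private_keywords[d] = sorted(keywords[k] for k in idx)
        cursor += spec.private_keywords_per_drug

    # heavy-tailed draw weights within the shared pool, so a handful of
    # very common keywords exceed the frequency filter while the pool's
    # tail stays informative
    shared_w = _power_law_weights(
        spec.shared_pool_size, 1.0, rng
    )
    background_w = _power_law_weights(spec.n_keywords, spec.keyword_frequency_tail, rng)

    # report roster; a configurable fraction of drugs never appears
    n_missing = int(round(spec.missing_drug_fraction * spec.n_drugs))
    missing = set(
        rng.choice(spec.n_drugs, size=n_missing, replace=False).tolist()
    )
    reported_drugs = [d for i, d in enumerate(drug_ids) if i not in missing]

    reports: list[Report] = []
    isr = 0
    for d in reported_drugs:
        c = drug_class[d]
        sig = class_keywords[c]
        classmates = [
            d2 for d2 in reported_drugs if drug_class[d2] == c and d2 != d
        ]
        for _ in range(spec.reports_per_drug):
            isr += 1
            entries = [DrugEntry(d, "PS")]
            if classmates and rng.random() < 0.15:
                entries.append(DrugEntry(str(rng.choice(classmates)), "SS"))
            if rng.random() < 0.25:
                entries.append(
                    DrugEntry(str(rng.choice(drug_ids)), str(rng.choice(["C", "I"])))
                )
            n_kw = max(1, rng.poisson(spec.keywords_per_report))
            kws: set[str] = set()
            priv = private_keywords[d]
            for _ in range(n_kw):
                u = rng.random()
                if u < spec.class_keyword_overlap:
                    kws.add(
                        keywords[shared_pool[rng.choice(spec.shared_pool_size, p=shared_w)]]
                    )
                elif u < spec.class_keyword_overlap + spec.private_keyword_rate and priv:
                    kws.add(priv[rng.integers(len(priv))])
                else:
                    kws.add(sig[rng.integers(len(sig))])
            n_bg = rng.poisson(spec.background_rate)
            if n_bg:
                kws |= {
                    keywords[k]
                    for k in rng.choice(spec.n_keywords, size=n_bg, p=background_w)
                }
            reports.append(Report(f"ISR{isr:07d}", entries, kws))
    report_set = ReportSet(reports)

    # fingerprints: common block + class block + per-drug noise flips.
    # Tanimoto(between) ~ c/(c+2s); Tanimoto(within) ~ (c+s-2m)/(c+s+2m)
    # for m flipped class bits, solved approximately from the target bands.
    s_bits = 40
    c_bits = max(
        1,
        int(round(spec.chem_between_class * 2 * s_bits / (1 - spec.chem_between_class))),
    )
    m_flips = max(
        0,
        int(round((c_bits + s_bits) * (1 - spec.chem_within_class)
                  / (2 * (1 + spec.chem_within_class)))),
    )
    total_on = c_bits + spec.n_drug_classes * s_bits
    if total_on + m_flips > spec.n_fingerprint_bits:
        raise ValueError("n_fingerprint_bits too small for the requested bands")
    common = np.arange(c_bits)
    class_bits = {
        c: np.arange(c_bits + c * s_bits, c_bits + (c + 1) * s_bits)
        for c in range(spec.n_drug_classes)
    }
    free = np.arange(c_bits + spec.n_drug_classes * s_bits, spec.n_fingerprint_bits)
    fingerprints: dict[str, list[int]] = {}
    for d in drug_ids:
        fp = np.zeros(spec.n_fingerprint_bits, dtype=int)
        fp[common] = 1
        on = class_bits[drug_class[d]].copy()
        if m_flips:
            drop = rng.choice(len(on), size=m_flips, replace=False)
            keep = np.delete(on, drop)
            gain = rng.choice(free, size=m_flips, replace=False)
            fp[keep] = 1
            fp[gain] = 1
        else:
            fp[on] = 1
        fingerprints[d] = fp.tolist()

    # protein families: mutated copies of a family ancestor
    sequences: dict[str, str] = {}
    aa = np.array(list(AMINO_ACIDS))
    for fam in range(spec.n_target_families):
        ancestor = rng.choice(len(aa), size=spec.seq_length)
        for t in target_ids:
            if target_family[t] != fam:
                continue
            seq = ancestor.copy()
            mut = rng.random(spec.seq_length) < spec.seq_mutation_rate
            seq[mut] = rng.choice(len(aa), size=int(mut.sum()))
            sequences[t] = "".join(aa[seq])

    # gold standard: each drug hits each target of its class's assigned
    # family independently w.p. fidelity; fidelity 1 gives an exactly
    # block-structured interaction matrix
    interactions: list[tuple[str, str]] = []
    for d in drug_ids:
        fam = class_family[drug_class[d]]
        for t in target_ids:
            if target_family[t] == fam and rng.random() < spec.class_target_fidelity:
                interactions.append((d, t))

    truth = WorldTruth(
        spec=spec,
        drug_class=drug_class,
        target_family=target_family,
        class_family=class_family,
        interactions=interactions,
        class_keywords=class_keywords,
        private_keywords=private_keywords,
        reports=report_set,
        fingerprints=fingerprints,
        sequences=sequences,
        reported_drugs=reported_drugs,
    )
    if out_dir is not None:
        write_world(truth, out_dir)
    return truth


def write_world(truth: WorldTruth, out_dir: str | Path) -> None:
    """Write all fixture files consumed by the rest of the pipeline."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = truth.spec
    # split reports round-robin into quarters
    per_quarter: list[list[Report]] = [[] for _ in range(spec.n_quarters)]
    for i, r in enumerate(truth.reports.reports):
        per_quarter[i % spec.n_quarters].append(r)
    for qi, reps in enumerate(per_quarter):
        yy = 10
        write_quarter(
            ReportSet(reps),
            out / f"DRUG{yy}Q{qi + 1}.TXT",
            out / f"REAC{yy}Q{qi + 1}.TXT",
        )
    with open(out / "fingerprints.tsv", "w") as fh:
        for d in sorted(truth.fingerprints):
            bits = "".join(map(str, truth.fingerprints[d]))
            fh.write(f"{d}\t{bits}\n")
    with open(out / "targets.fasta", "w") as fh:
        for t in sorted(truth.sequences):
            fh.write(f">{t}\n{truth.sequences[t]}\n")
    with open(out / "gold_standard.tsv", "w") as fh:
        fh.write("drug_id\ttarget_id\n")
        for d, t in sorted(truth.interactions):
            fh.write(f"{d}\t{t}\n")
    manifest = {
        "spec": asdict(spec),
        "drug_class": truth.drug_class,
        "target_family": truth.target_family,
        "class_family": truth.class_family,
        "class_keywords": {str(c): kws for c, kws in truth.class_keywords.items()},
        "reported_drugs": truth.reported_drugs,
        "n_reports": len(truth.reports),
        "n_interactions": len(truth.interactions),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def shuffle_labels(
    gold: list[tuple[str, str]], seed: int, n_swaps_per_edge: int = 10
) -> list[tuple[str, str]]:
    """Degree-preserving rewiring of a bipartite edge list.

    Repeated double-edge swaps: pick edges (d1,t1), (d2,t2) and replace
    them with (d1,t2), (d2,t1) when that creates no duplicate edge.  Both
    the drug and target degree sequences and the edge count are preserved;
    any association between specific drugs and targets is destroyed.
    """
    rng = np.random.default_rng(seed)
    edges = sorted(set(gold))
    m = len(edges)
    if m < 2:
        return list(edges)
    edge_set = set(edges)
    target_swaps = n_swaps_per_edge * m
    done = 0
    attempts = 0
    max_attempts = 100 * target_swaps
    while done < target_swaps and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(m), rng.integers(m)
        if i == j:
            continue
        d1, t1 = edges[i]
        d2, t2 = edges[j]
        if d1 == d2 or t1 == t2:
            continue
        new1, new2 = (d1, t2), (d2, t1)
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i], edges[j] = new1, new2
        done += 1
    return sorted(edge_set)
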