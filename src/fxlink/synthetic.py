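"""Seeded generators for synthetic pipeline inputs with machine-readable truth.

Each generator derives its own child seed from one master seed via
``numpy.random.SeedSequence(entropy=master, spawn_key=(k,))`` with a fixed,
documented key per generator (0 proteome, 1 spectra, 2 abundance,
3 structure, 4 Ct), so every artefact is independently and exactly
reproducible. Text outputs are byte-identical under a fixed seed.

The generators emulate the statistical structure the analysis stages assume:
cross-linked peptide-pair spectra with +12/+24 Da precursor shifts, partial
fragment coverage with ppm jitter and uniform noise peaks at charge 4+..7+;
log-normal protein intensity tables over 3 conditions x 6 replicates with
planted log2 fold-changes and completely-at-random missingness; CA-trace toy
structures with planted near/far site pairs; and Ct tables with planted
ddCt effects on top of per-sample plate offsets.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, MassConstants
from .masscalc import Peptide, digest, fragment_neutral_masses, peptide_mass
from .proteome_quant import AbundanceTable, COMPARTMENTS
from .xl_search import SpectrumRecord

__all__ = [
    "child_rng",
    "gen_proteome",
    "gen_xl_spectra",
    "gen_abundance",
    "gen_structure_toy",
    "gen_ct",
    "make_fixtures",
]

# Approximate human amino-acid frequencies (percent); keeps K/R density — and
# hence tryptic peptide lengths — realistic.
AA_FREQS = {
    "A": 7.0, "R": 5.6, "N": 3.6, "D": 4.7, "C": 2.3, "Q": 4.8, "E": 7.1,
    "G": 6.6, "H": 2.6, "I": 4.3, "L": 10.0, "K": 5.7, "M": 2.1, "F": 3.7,
    "P": 6.3, "S": 8.3, "T": 5.3, "W": 1.2, "Y": 2.7, "V": 6.0,
}

_SEED_KEYS = {"proteome": 0, "spectra": 1, "abundance": 2, "structure": 3, "ct": 4}


def child_rng(master_seed: int, generator: str) -> np.random.Generator:
    """Deterministic per-generator RNG fanned out from one master seed."""
    key = _SEED_KEYS[generator]
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(key,))
    )


def gen_proteome(
    n_proteins: int = 30,
    mean_length: int = 300,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Random protein sequences with natural residue frequencies.

    Returns (accession, sequence) pairs and a protein -> compartment map drawn
    over the nine subcellular localisations.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = child_rng(seed, "proteome")
    letters = np.array(list(AA_FREQS))
    probs = np.array(list(AA_FREQS.values()))
    probs = probs / probs.sum()
    proteome = []
    localisation = {}
    for i in range(n_proteins):
        length = max(60, int(rng.normal(mean_length, 0.2 * mean_length)))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        acc = f"SYN{i:04d}"
        proteome.append((acc, seq))
        localisation[acc] = str(rng.choice(COMPARTMENTS))
    return proteome, localisation


def _pick_site(rng: np.random.Generator, sequence: str) -> int:
    """1-based linker site within a peptide, preferring K/R positions."""
    kr = [i + 1 for i, r in enumerate(sequence) if r in "KR"]
    if kr:
        return int(rng.choice(kr))
    n = len(sequence)
    return 1 + (n - 1) // 2  # middle residue, N-terminal tie-break


def gen_xl_spectra(
    proteome: Sequence[tuple[str, str]],
    n_links: int = 40,
    coverage: float = 0.85,
    noise_peaks: int = 5,
    ppm_sigma: float = 2.0,
    ms1_sigma: float = 1.5,
    charges: tuple[int, int] = (4, 7),
    n_replicates: int = 3,
    condition: str = "undiff",
    intra_fraction: float = 0.3,
    double_fraction: float = 0.0,
    emit_unshifted_twins: bool = False,
    peptide_length_range: tuple[int, int] = (10, 16),
    seed: int = 0,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> tuple[dict[str, list[SpectrumRecord]], dict]:
    """Cross-linked peptide-pair MS2 spectra with full ground truth.

    One spectrum per planted link per replicate. Linker sites sit
    preferentially on K/R. Fragments containing the site are emitted as
    +12 Da shifted ions, fragments outside it unshifted; each ion slot
    (y ladder at 1+/2+, b ladder at 1+) is emitted independently with
    probability ``coverage``, with Gaussian ppm jitter truncated inside the
    matching tolerances. Noise peaks are uniform in m/z with intensities below
    the median true-fragment intensity. ``emit_unshifted_twins`` additionally
    emits unshifted copies of site-containing ions (linker cleavage during
    fragmentation).
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    rng = child_rng(seed, "spectra")

    candidates: dict[str, list[Peptide]] = {}
    for acc, seq in proteome:
        peps = [
            p for p in digest(seq, max_missed=2, length_range=peptide_length_range,
                              protein_id=acc)
        ]
        if peps:
            candidates[acc] = peps
    accs = sorted(candidates)
    if len(accs) < 2:
        raise ValueError("need at least two proteins with usable peptides")
    n_peptides = sum(len(v) for v in candidates.values())
    if n_links > n_peptides * (n_peptides - 1) // 2:
        raise ValueError("requested links exceed available residue pairs")

    links = []
    seen: set[tuple] = set()
    attempts = 0
    while len(links) < n_links:
        attempts += 1
        if attempts > 200 * n_links + 1000:
            raise ValueError("requested links exceed available residue pairs")
        intra = rng.random() < intra_fraction
        if intra:
            acc_a = acc_b = accs[rng.integers(len(accs))]
            if len(candidates[acc_a]) < 2:
                continue
        else:
            ia, ib = rng.choice(len(accs), size=2, replace=False)
            acc_a, acc_b = accs[ia], accs[ib]
        pep_a = candidates[acc_a][rng.integers(len(candidates[acc_a]))]
        pep_b = candidates[acc_b][rng.integers(len(candidates[acc_b]))]
        if (pep_a.protein_id, pep_a.start) == (pep_b.protein_id, pep_b.start):
            continue
        site_a = _pick_site(rng, pep_a.sequence)
        site_b = _pick_site(rng, pep_b.sequence)
        key = tuple(sorted([
            (acc_a, pep_a.start + site_a - 1), (acc_b, pep_b.start + site_b - 1)
        ]))
        if key in seen:
            continue
        seen.add(key)
        linker_count = 2 if rng.random() < double_fraction else 1
        links.append((pep_a, site_a, pep_b, site_b, linker_count))

    spectra_by_rep: dict[str, list[SpectrumRecord]] = {}
    truth_links = []
    truth_spectra: dict[str, dict] = {}
    for li, (pep_a, site_a, pep_b, site_b, linker_count) in enumerate(links):
        truth_links.append(
            {
                "protein_a": pep_a.protein_id, "protein_b": pep_b.protein_id,
                "peptide_a": pep_a.sequence, "peptide_b": pep_b.sequence,
                "start_a": pep_a.start, "start_b": pep_b.start,
                "site_a": site_a, "site_b": site_b,
                "site_a_protein": pep_a.start + site_a - 1,
                "site_b_protein": pep_b.start + site_b - 1,
                "linker_count": linker_count,
            }
        )
    ms1_tol, ms2_tol = 6.0, 8.0
    for rep in range(1, n_replicates + 1):
        rep_id = f"rep{rep}"
        spectra: list[SpectrumRecord] = []
        for li, (pep_a, site_a, pep_b, site_b, linker_count) in enumerate(links):
            z = int(rng.integers(charges[0], charges[1] + 1))
            linker_mass = constants.linker_single * linker_count
            m_neutral = (
                peptide_mass(pep_a, constants) + peptide_mass(pep_b, constants)
                + linker_mass
            )
            jitter1 = np.clip(rng.normal(0.0, ms1_sigma), -(ms1_tol - 0.5), ms1_tol - 0.5)
            mz = (m_neutral + z * constants.proton) / z * (1 + 1e-6 * jitter1)

            peaks_mz, peaks_int = [], []
            emitted = {"a": 0, "b": 0}
            for side, (pep, site) in zip(
                ("a", "b"), ((pep_a, site_a), (pep_b, site_b))
            ):
                neutrals = fragment_neutral_masses(pep.sequence, constants)
                n = len(pep.sequence)
                # y ions at 1+/2+, b ions at 1+ (y ions dominate HCD spectra)
                for series, frag_charges in (("y", (1, 2)), ("b", (1,))):
                    base = neutrals[series]
                    for i in range(1, n):
                        contains = (i >= n - site + 1) if series == "y" else (i >= site)
                        for zf in frag_charges:
                            forms = [contains]
                            if contains and emit_unshifted_twins:
                                forms.append(False)
                            for shifted in forms:
                                if rng.random() >= coverage:
                                    continue
                                shift = constants.linker_single if shifted else 0.0
                                theo = (base[i - 1] + shift + zf * constants.proton) / zf
                                jit = np.clip(
                                    rng.normal(0.0, ppm_sigma),
                                    -(ms2_tol - 0.5), ms2_tol - 0.5,
                                )
                                peaks_mz.append(theo * (1 + 1e-6 * jit))
                                peaks_int.append(rng.lognormal(np.log(1000.0), 0.5))
                                emitted[side] += 1
            median_int = float(np.median(peaks_int)) if peaks_int else 100.0
            for _ in range(noise_peaks):
                peaks_mz.append(rng.uniform(200.0, 1800.0))
                peaks_int.append(rng.uniform(0.05, 0.5) * median_int)
            order = np.argsort(peaks_mz)
            peaks = np.column_stack([np.array(peaks_mz)[order], np.array(peaks_int)[order]])
            sid = f"{condition}.{rep_id}.scan{li:04d}"
            spectra.append(
                SpectrumRecord(
                    spectrum_id=sid, precursor_mz=float(mz), precursor_charge=z,
                    peaks=peaks, replicate_id=rep_id, condition=condition,
                )
            )
            truth_spectra[sid] = {
                "link_index": li, "emitted_a": emitted["a"], "emitted_b": emitted["b"],
                "charge": z,
            }
        spectra_by_rep[rep_id] = spectra

    truth = {
        "condition": condition,
        "links": truth_links,
        "spectra": truth_spectra,
        "params": {
            "n_links": n_links, "coverage": coverage, "noise_peaks": noise_peaks,
            "ppm_sigma": ppm_sigma, "ms1_sigma": ms1_sigma,
            "n_replicates": n_replicates, "seed": seed,
        },
    }
    return spectra_by_rep, truth


def gen_abundance(
    n_proteins: int = 1000,
    conditions: Sequence[str] = ("undiff", "RA", "RA_PMA"),
    replicates: int = 6,
    n_planted: int = 50,
    effect_log2: float = 1.5,
    sigma: float = 0.3,
    missing_rate: float = 0.10,
    effect_condition: str = "RA",
    seed: int = 0,
) -> tuple[AbundanceTable, dict]:
    """Log-normal intensity/iBAQ tables with planted log2 fold-changes.

    Effects (half up, half down, magnitude ``effect_log2``) are planted in
    ``effect_condition`` relative to all other conditions. Missingness is
    completely at random at ``missing_rate``.
    """
    if n_proteins <= 0 or replicates <= 0 or sigma <= 0:
        raise ValueError("parameters must be positive")
    rng = child_rng(seed, "abundance")
    proteins = [f"SYN{i:04d}" for i in range(n_proteins)]
    base = rng.normal(25.0, 2.0, size=n_proteins)
    planted_idx = rng.choice(n_proteins, size=n_planted, replace=False)
    effects = np.zeros(n_proteins)
    signs = np.where(np.arange(n_planted) % 2 == 0, 1.0, -1.0)
    effects[planted_idx] = signs * effect_log2

    samples, cond_of = [], []
    for cond in conditions:
        for r in range(1, replicates + 1):
            samples.append(f"{cond}_{r}")
            cond_of.append(cond)
    design = pd.DataFrame(
        {"condition": cond_of, "replicate": [int(s.rsplit("_", 1)[1]) for s in samples]},
        index=pd.Index(samples, name="sample_id"),
    )

    log2 = np.empty((n_proteins, len(samples)))
    for j, cond in enumerate(cond_of):
        mean = base + (effects if cond == effect_condition else 0.0)
        log2[:, j] = mean + rng.normal(0.0, sigma, size=n_proteins)
    intensity = pd.DataFrame(2.0 ** log2, index=proteins, columns=samples)
    mask = rng.random(intensity.shape) < missing_rate
    intensity = intensity.mask(mask)

    peptide_counts = pd.Series(rng.integers(5, 40, size=n_proteins), index=proteins)
    ibaq = intensity.div(peptide_counts, axis=0)
    table = AbundanceTable(intensity=intensity, design=design, ibaq=ibaq)
    truth = {
        "planted": {proteins[i]: float(effects[i]) for i in planted_idx},
        "effect_condition": effect_condition,
        "sigma": sigma,
        "missing_rate": missing_rate,
        "peptide_counts": peptide_counts.to_dict(),
        "seed": seed,
    }
    return table, truth


def gen_structure_toy(
    protein_sequences: Sequence[tuple[str, str]],
    planted_pairs: Sequence[tuple[str, int, str, int, float]],
    seed: int = 0,
    copies: Mapping[str, int] | None = None,
) -> tuple["object", dict]:
    """CA-trace toy structure with controlled inter-site distances.

    ``planted_pairs`` are (acc_a, protein_site_a, acc_b, protein_site_b,
    distance_Å): the second site's CA is placed exactly ``distance`` away from
    the first site's CA. ``copies`` may request extra translated copies of a
    protein's chain (homo-oligomer cases). Returns a StructureModel plus truth
    with the planted distances and expected verdicts at the 30 Å restraint.
    """
    from .struct_validate import SATISFIED, OVER_LENGTH, ChainModel, StructureModel

    rng = child_rng(seed, "structure")
    copies = dict(copies or {})
    chain_ids = iter("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    chains: list[ChainModel] = []
    coords_by_acc: dict[str, np.ndarray] = {}
    for k, (acc, seq) in enumerate(protein_sequences):
        n = len(seq)
        xyz = np.column_stack([
            3.8 * np.arange(n), np.full(n, 100.0 * k), np.zeros(n)
        ]).astype(float)
        coords_by_acc[acc] = xyz
        chains.append((acc, seq, xyz))

    used: set[tuple[str, int]] = set()
    for acc_a, site_a, acc_b, site_b, distance in planted_pairs:
        if (acc_b, site_b) in used:
            raise ValueError(f"residue {acc_b}:{site_b} planted twice")
        used.add((acc_b, site_b))
        anchor = coords_by_acc[acc_a][site_a - 1]
        # random direction keeps the geometry non-axis-aligned
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        coords_by_acc[acc_b][site_b - 1] = anchor + distance * v

    models = []
    for acc, seq, xyz in chains:
        n_copies = copies.get(acc, 1)
        for c in range(n_copies):
            shift = np.array([0.0, 0.0, 500.0 * c])
            models.append(
                ChainModel(
                    chain_id=next(chain_ids), sequence=seq,
                    ca_xyz=xyz + shift, author_numbers=np.arange(1, len(seq) + 1),
                )
            )
    model = StructureModel("SYNTOY", models)
    truth_pairs = []
    for acc_a, site_a, acc_b, site_b, distance in planted_pairs:
        # classify on the realised coordinate distance (float rounding can
        # land a hair off the requested value)
        realised = float(np.linalg.norm(
            coords_by_acc[acc_a][site_a - 1] - coords_by_acc[acc_b][site_b - 1]
        ))
        truth_pairs.append(
            {
                "protein_a": acc_a, "site_a": site_a,
                "protein_b": acc_b, "site_b": site_b,
                "distance": realised,
                "verdict": SATISFIED if realised <= 30.0 else OVER_LENGTH,
            }
        )
    return model, {"pairs": truth_pairs, "seed": seed}


def write_structure_cif(model: "object", path: str | Path) -> None:
    """Write a CA-trace StructureModel as mmCIF via gemmi."""
    import gemmi

    from .struct_validate import ONE_TO_THREE

    st = gemmi.Structure()
    st.name = model.structure_id
    gm = gemmi.Model("1")
    for chain in model.chains:
        gc = gemmi.Chain(chain.chain_id)
        for i, (one, xyz, num) in enumerate(
            zip(chain.sequence, chain.ca_xyz, chain.author_numbers)
        ):
            res = gemmi.Residue()
            res.name = ONE_TO_THREE[one]
            res.seqid = gemmi.SeqId(int(num), " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            atom.b_iso = 20.0
            res.add_atom(atom)
            gc.add_residue(res)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    st.make_mmcif_document().write_file(str(path))


def gen_ct(
    planted_ddct: Mapping[str, Mapping[str, float]],
    conditions: Sequence[str] = ("undiff", "RA", "RA_PMA"),
    control_condition: str = "undiff",
    replicates: int = 6,
    technical_reps: int = 2,
    ct_sigma: float = 0.2,
    ref_gene: str = "HPRT1",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Ct tables with planted ddCt effects.

    ``planted_ddct[gene][condition]`` is the shift relative to the control
    condition (negative = induction). Per-sample plate offsets are added to
    every Ct in a sample; they must cancel through the reference gene.
    """
    rng = child_rng(seed, "ct")
    genes = sorted(planted_ddct)
    base_dct = {g: float(rng.uniform(2.0, 8.0)) for g in genes}
    rows = []
    for cond in conditions:
        for r in range(1, replicates + 1):
            sample = f"{cond}_{r}"
            plate = float(rng.normal(0.0, 0.5))
            ref_ct = 20.0 + plate + float(rng.normal(0.0, ct_sigma))
            for t in range(1, technical_reps + 1):
                rows.append(
                    {"gene": ref_gene, "sample_id": sample, "condition": cond,
                     "replicate": r, "technical_rep": t,
                     "ct": ref_ct + float(rng.normal(0.0, 0.05))}
                )
            for g in genes:
                shift = float(planted_ddct[g].get(cond, 0.0))
                if cond == control_condition:
                    shift = 0.0
                ct = ref_ct + base_dct[g] + shift + float(rng.normal(0.0, ct_sigma))
                for t in range(1, technical_reps + 1):
                    rows.append(
                        {"gene": g, "sample_id": sample, "condition": cond,
                         "replicate": r, "technical_rep": t,
                         "ct": ct + float(rng.normal(0.0, 0.05))}
                    )
    table = pd.DataFrame(rows)
    truth = {
        "planted_ddct": {g: dict(v) for g, v in planted_ddct.items()},
        "base_dct": base_dct,
        "ref_gene": ref_gene,
        "control_condition": control_condition,
        "ct_sigma": ct_sigma,
        "seed": seed,
    }
    return table, truth


PRESETS = {
    "default": {
        "n_proteins": 30, "mean_length": 300, "n_links": 40, "coverage": 0.85,
        "noise_peaks": 5, "n_replicates": 3,
        "conditions": ("undiff", "RA", "RA_PMA"),
    },
    "small": {
        "n_proteins": 10, "mean_length": 200, "n_links": 8, "coverage": 0.9,
        "noise_peaks": 3, "n_replicates": 3,
        "conditions": ("undiff",),
    },
}


def make_fixtures(out_dir: str | Path, seed: int = 17, preset: str = "default") -> dict:
    """Write a complete fixture set (FASTA, MGF, tables, mmCIF, Ct, truth JSON)."""
    from .io import write_fasta, write_mgf

    cfg = PRESETS[preset]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteome, localisation = gen_proteome(cfg["n_proteins"], cfg["mean_length"], seed)
    write_fasta(proteome, out / "proteome.fasta")
    pd.DataFrame(
        sorted(localisation.items()), columns=["protein", "compartment"]
    ).to_csv(out / "localisation.tsv", sep="\t", index=False)

    truth: dict = {"seed": seed, "preset": preset, "xl": {}, "mgf": {}}
    for ci, cond in enumerate(cfg["conditions"]):
        spectra_by_rep, xl_truth = gen_xl_spectra(
            proteome, n_links=cfg["n_links"], coverage=cfg["coverage"],
            noise_peaks=cfg["noise_peaks"], n_replicates=cfg["n_replicates"],
            condition=cond, seed=seed + ci,
        )
        truth["xl"][cond] = xl_truth
        truth["mgf"][cond] = {}
        for rep_id, spectra in spectra_by_rep.items():
            path = out / f"xl_{cond}_{rep_id}.mgf"
            write_mgf(
                (
                    {"spectrum_id": s.spectrum_id, "precursor_mz": s.precursor_mz,
                     "precursor_charge": s.precursor_charge, "peaks": s.peaks}
                    for s in spectra
                ),
                path,
            )
            truth["mgf"][cond][rep_id] = path.name

    table, ab_truth = gen_abundance(seed=seed)
    table.intensity.rename_axis("protein").to_csv(out / "intensity.tsv", sep="\t")
    table.ibaq.rename_axis("protein").to_csv(out / "ibaq.tsv", sep="\t")
    table.design.to_csv(out / "design.tsv", sep="\t")
    truth["abundance"] = ab_truth

    two = proteome[:2]
    pairs = [
        (two[0][0], 20, two[1][0], 30, 12.0),
        (two[0][0], 50, two[1][0], 60, 45.0),
    ]
    model, st_truth = gen_structure_toy(two, pairs, seed=seed)
    write_structure_cif(model, out / "toy_structure.cif")
    truth["structure"] = st_truth

    ct, ct_truth = gen_ct(
        {"TGM2": {"RA": -2.0, "RA_PMA": -2.0}, "SYN1": {}, "RET": {"RA": -1.0}},
        seed=seed,
    )
    ct.to_csv(out / "ct.tsv", sep="\t", index=False)
    truth["ct"] = ct_truth

    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return truth
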