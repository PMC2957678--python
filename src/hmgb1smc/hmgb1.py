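"""The HMGB1 signal-transduction network.

Encodes the crosstalk model of HMGB1-driven proliferation signaling: the
ligand HMGB1 activates a lumped receptor (RAGE standing in for RAGE and the
toll-like receptors), which drives three coupled pathways,

* p53-MDM2: PI3K -> PIP3 -> AKT -> MDM2 -| p53 -> MDM2 (negative feedback,
  the oscillator) plus the positive loop p53 -> PTEN -| PIP3;
* RAS-ERK: RAS -> RAF -> MEK -> ERK -> CyclinD (and Myc);
* Rb-E2F: CyclinD -| Rb -| E2F -> CyclinE -| Rb, with the Rb-E2F complex RE;

with the crosstalk edges RAS -> PI3K, E2F -> ARF -| MDM2, p53 -> P21 -|
CyclinD/E and INK4A -| CyclinD.  Proteins with suffix "_a"/"_p" are the
active/phosphorylated forms; the total of active + inactive forms of RAGE,
PI3K, PIP, AKT, RAS, RAF, MEK and ERK is conserved.  mdm2 (lower case) is the
explicit mRNA transcript of MDM2.  Protein synthesis of PTEN, MDM2 (via the
transcript), CyclinD, Myc, E2F and CyclinE follows Hill kinetics; every other
reaction is elementary mass action.  31 species, 59 reactions.

Units: minutes and molecule counts.

Rate constants: most kinetic constants of this pathway are not individually
measured; the defaults below are this package's own calibration, chosen once
so that the default network reproduces the qualitative behaviors documented
in docs/methods.md (CyclinE peaking near the G1-S point at ~600 min, p53
first-peak dose response to HMGB1, sustained stochastic vs damped
deterministic p53/MDM2_p oscillations, and the mutation-sweep directions).
Treat them as a self-consistent set, not as measurements.
"""

from __future__ import annotations

from .reaction_model import (
    ConfigurationError,
    ConservationRelation,
    Hill,
    MassAction,
    ParameterSet,
    Reaction,
    ReactionNetwork,
    SpeciesDef,
)

__all__ = ["DEFAULT_PARAMETERS", "PARAMETER_NOTES", "build_hmgb1_network"]


#: Calibrated default rate constants (per minute; see module docstring).
DEFAULT_PARAMETERS: dict[str, float] = {
    # receptor layer
    "k_rage_act": 4e-05,      # per HMGB1 molecule, RAGE activation
    "k_rage_deact": 0.36,
    "d_HMGB1": 1.0e-5,         # slow extracellular clearance of the ligand
    # PI3K / PIP3 / AKT
    "k_pi3k_act": 7.93959e-05,      # per RAGE_a molecule
    "k_pi3k_act_ras": 7.71127e-06,  # crosstalk: per RAS_a molecule
    "k_pi3k_deact": 0.129577,
    "k_pip3_gen": 1.26192e-06,      # per PI3K_a molecule
    "k_pip3_dephos": 0.000424047,     # basal PIP3 -> PIP2
    "k_pten_hyd": 4.25384e-07,      # per PTEN molecule, PIP3 -> PIP2
    "k_akt_act": 4.36682e-08,       # per PIP3 molecule
    "k_akt_basal": 3.90897e-05,     # receptor-independent AKT phosphorylation
    "k_akt_deact": 0.0146592,
    # p53 core
    "k_p53_syn": 2578.0,        # molecules/min, constitutive synthesis
    "d_p53": 0.00734035,             # basal decay
    "d_p53_mdm2": 7.72356e-06,      # per MDM2_p molecule, ubiquitination-driven
    # mdm2 transcript and MDM2 protein
    "v_mdm2_syn": 725.265,       # max transcription rate (p53-driven, Hill)
    "K_mdm2_syn": 45604.0,
    "n_mdm2_syn": 8.65,
    "d_mdm2_mrna": 0.0290924,
    "k_mdm2_tln": 9.7825,         # translation, per transcript
    "d_mdm2": 0.0287242,
    "k_mdm2_phos": 1.3347e-05,     # per AKT_p molecule
    "k_mdm2_dephos": 0.0295191,
    "d_mdm2p": 0.134547,
    "d_ARF": 3.0e-6,           # per ARF molecule, MDM2 degradation (mutation knob)
    # PTEN
    "v_pten_syn": 13.3706,
    "K_pten_syn": 73271.2,
    "n_pten_syn": 15.2327,
    "d_pten": 0.363059,
    # ARF / P21 / INK4A
    "k_arf_syn": 0.0125667,         # per E2F molecule
    "d_arf": 0.02,
    "k_p21_syn": 0.00011,       # per p53 molecule
    "d_p21_decay": 0.00387363,
    "d_P21": 2e-05,           # per P21 molecule, Cyclin degradation (mutation knob)
    "k_ink4a_syn": 20.0178,
    "d_ink4a": 0.02,
    "d_cd_ink4a": 5.13143e-06,      # per INK4A molecule
    # RAS-ERK cascade
    "k_ras_act": 0.0002,       # per RAGE_a molecule
    "d_RAS": 0.01,             # RAS deactivation (mutation knob)
    "k_raf_act": 1.2e-06,       # per RAS_a molecule
    "k_raf_deact": 0.032,
    "k_mek_act": 3.97474e-06,       # per RAF_a molecule
    "k_mek_deact": 0.0324114,
    "k_erk_act": 4e-06,       # per MEK_p molecule
    "k_erk_deact": 0.032,
    # CyclinD / Myc
    "v_cd_syn": 31.0,
    "K_cd_syn": 2000.0,
    "n_cd_syn": 4.18227,
    "d_cd": 0.00568529,
    "v_myc_syn": 10.4845,
    "K_myc_syn": 4200.0,
    "n_myc_syn": 4.0,
    "d_myc": 0.00557393,
    # Rb / E2F / RE / CyclinE
    "k_re_cd": 4e-07,         # per CyclinD molecule, E2F release from RE
    "k_re_myc": 3.00272e-07,        # per Myc molecule
    "k_re_ce": 2.5e-07,         # per CyclinE molecule
    "k_re_bind": 8.53039e-06,       # Rb + E2F association
    "k_rb_syn": 10.0,
    "d_rb": 0.0106827,
    "k_rb_cd": 1.0e-6,         # per CyclinD molecule, removal of free Rb
    "k_rb_ce": 1.0e-6,         # per CyclinE molecule
    "v_e2f_syn": 4.59133,
    "K_e2f_syn": 2197.06,
    "n_e2f_syn": 3.39284,
    "d_e2f": 0.02,
    "v_ce_syn": 59.863,
    "K_ce_syn": 2500.0,
    "n_ce_syn": 4.0,
    "d_ce": 0.00800129,
}

#: Cross-references to the alternative symbols used in the deterministic
#: (ODE) formulation of the model, for the three mutation knobs.
PARAMETER_NOTES: dict[str, str] = {
    "d_ARF": "MDM2 degradation rate driven by ARF (d'7 in the ODE formulation)",
    "d_P21": "Cyclin degradation rate driven by P21 (b'6 in the ODE formulation)",
    "d_RAS": "RAS deactivation rate (b1 in the ODE formulation)",
}

#: Initial molecule counts of the species that start nonzero (all others 0).
TABLE1_INITIAL_COUNTS: dict[str, float] = {
    "RAGE": 1.0e3,
    "PI3K": 1.0e5,
    "PIP2": 1.0e5,
    "AKT": 1.0e5,
    "MDM2": 1.0e4,
    "MDM2_p": 2.0e4,
    "p53": 2.0e4,
    "RAS": 1.0e4,
    "RAF": 1.0e4,
    "MEK": 1.0e4,
    "ERK": 1.0e4,
    "RE": 1.0e5,
}

_CONSERVED_PAIRS = [
    ("RAGE", "RAGE_a"),
    ("PI3K", "PI3K_a"),
    ("PIP2", "PIP3"),
    ("AKT", "AKT_p"),
    ("RAS", "RAS_a"),
    ("RAF", "RAF_a"),
    ("MEK", "MEK_p"),
    ("ERK", "ERK_p"),
]


def _species(hmgb1_init: float) -> list[SpeciesDef]:
    init = dict(TABLE1_INITIAL_COUNTS)
    sp: list[SpeciesDef] = [
        SpeciesDef("HMGB1", hmgb1_init, role="ligand"),
        SpeciesDef("RAGE", init["RAGE"], role="receptor"),
        SpeciesDef("RAGE_a", 0.0, role="receptor", variant_of="RAGE"),
        SpeciesDef("PI3K", init["PI3K"]),
        SpeciesDef("PI3K_a", 0.0, variant_of="PI3K"),
        SpeciesDef("PIP2", init["PIP2"], role="lipid"),
        SpeciesDef("PIP3", 0.0, role="lipid", variant_of="PIP2"),
        SpeciesDef("AKT", init["AKT"]),
        SpeciesDef("AKT_p", 0.0, variant_of="AKT"),
        SpeciesDef("p53", init["p53"]),
        SpeciesDef("mdm2", 0.0, role="mRNA"),
        SpeciesDef("MDM2", init["MDM2"]),
        SpeciesDef("MDM2_p", init["MDM2_p"], variant_of="MDM2"),
        SpeciesDef("PTEN", 0.0),
        SpeciesDef("ARF", 0.0),
        SpeciesDef("P21", 0.0),
        SpeciesDef("INK4A", 0.0),
        SpeciesDef("RAS", init["RAS"]),
        SpeciesDef("RAS_a", 0.0, variant_of="RAS"),
        SpeciesDef("RAF", init["RAF"]),
        SpeciesDef("RAF_a", 0.0, variant_of="RAF"),
        SpeciesDef("MEK", init["MEK"]),
        SpeciesDef("MEK_p", 0.0, variant_of="MEK"),
        SpeciesDef("ERK", init["ERK"]),
        SpeciesDef("ERK_p", 0.0, variant_of="ERK"),
        SpeciesDef("Myc", 0.0),
        SpeciesDef("CyclinD", 0.0),
        SpeciesDef("CyclinE", 0.0),
        SpeciesDef("E2F", 0.0),
        SpeciesDef("Rb", 0.0),
        SpeciesDef("RE", init["RE"], role="complex"),
    ]
    return sp


def build_hmgb1_network(
    params: ParameterSet | None = None,
    hmgb1_init: float = 1.0e3,
) -> ReactionNetwork:
    """Build the 31-species / 59-reaction HMGB1 network.

    ``params`` defaults to :data:`DEFAULT_PARAMETERS`; a
    :class:`~hmgb1smc.reaction_model.ConfigurationError` names any missing
    constant.  ``hmgb1_init`` sets the initial HMGB1 ligand count (the main
    experimental dose knob).
    """
    if params is None:
        params = ParameterSet(DEFAULT_PARAMETERS, PARAMETER_NOTES)
    p = params  # p["name"] raises ConfigurationError when absent

    def ma(label: str, reactants: list[str], products: list[str], k_name: str) -> Reaction:
        return Reaction(label, tuple(reactants), tuple(products), MassAction(p[k_name]))

    def hill(label: str, product: str, prefix: str, regulator: str) -> Reaction:
        return Reaction(
            label,
            (),
            (product,),
            Hill(
                vmax=p[f"v_{prefix}"],
                K=p[f"K_{prefix}"],
                n=p[f"n_{prefix}"],
                regulator=regulator,
            ),
        )

    rxns = [
        # receptor layer
        ma("rage_activation", ["HMGB1", "RAGE"], ["HMGB1", "RAGE_a"], "k_rage_act"),
        ma("rage_deactivation", ["RAGE_a"], ["RAGE"], "k_rage_deact"),
        ma("hmgb1_clearance", ["HMGB1"], [], "d_HMGB1"),
        # PI3K / PIP / AKT
        ma("pi3k_activation", ["RAGE_a", "PI3K"], ["RAGE_a", "PI3K_a"], "k_pi3k_act"),
        ma("pi3k_activation_by_ras", ["RAS_a", "PI3K"], ["RAS_a", "PI3K_a"], "k_pi3k_act_ras"),
        ma("pi3k_deactivation", ["PI3K_a"], ["PI3K"], "k_pi3k_deact"),
        ma("pip3_generation", ["PI3K_a", "PIP2"], ["PI3K_a", "PIP3"], "k_pip3_gen"),
        ma("pip3_hydrolysis_pten", ["PTEN", "PIP3"], ["PTEN", "PIP2"], "k_pten_hyd"),
        ma("pip3_dephosphorylation", ["PIP3"], ["PIP2"], "k_pip3_dephos"),
        ma("akt_activation", ["PIP3", "AKT"], ["PIP3", "AKT_p"], "k_akt_act"),
        ma("akt_basal_activation", ["AKT"], ["AKT_p"], "k_akt_basal"),
        ma("akt_deactivation", ["AKT_p"], ["AKT"], "k_akt_deact"),
        # p53 core
        ma("p53_synthesis", [], ["p53"], "k_p53_syn"),
        ma("p53_decay", ["p53"], [], "d_p53"),
        ma("p53_degradation_mdm2", ["MDM2_p", "p53"], ["MDM2_p"], "d_p53_mdm2"),
        # mdm2 transcript / MDM2
        hill("mdm2_transcription", "mdm2", "mdm2_syn", "p53"),
        ma("mdm2_mrna_decay", ["mdm2"], [], "d_mdm2_mrna"),
        ma("mdm2_translation", ["mdm2"], ["mdm2", "MDM2"], "k_mdm2_tln"),
        ma("mdm2_degradation", ["MDM2"], [], "d_mdm2"),
        ma("mdm2_phosphorylation", ["AKT_p", "MDM2"], ["AKT_p", "MDM2_p"], "k_mdm2_phos"),
        ma("mdm2_dephosphorylation", ["MDM2_p"], ["MDM2"], "k_mdm2_dephos"),
        ma("mdm2p_degradation", ["MDM2_p"], [], "d_mdm2p"),
        ma("mdm2p_degradation_arf", ["ARF", "MDM2_p"], ["ARF"], "d_ARF"),
        ma("mdm2_degradation_arf", ["ARF", "MDM2"], ["ARF"], "d_ARF"),
        # PTEN
        hill("pten_synthesis", "PTEN", "pten_syn", "p53"),
        ma("pten_degradation", ["PTEN"], [], "d_pten"),
        # ARF / P21 / INK4A
        ma("arf_synthesis", ["E2F"], ["E2F", "ARF"], "k_arf_syn"),
        ma("arf_degradation", ["ARF"], [], "d_arf"),
        ma("p21_synthesis", ["p53"], ["p53", "P21"], "k_p21_syn"),
        ma("p21_degradation", ["P21"], [], "d_p21_decay"),
        ma("cyclind_degradation_p21", ["P21", "CyclinD"], ["P21"], "d_P21"),
        ma("cycline_degradation_p21", ["P21", "CyclinE"], ["P21"], "d_P21"),
        ma("ink4a_synthesis", [], ["INK4A"], "k_ink4a_syn"),
        ma("ink4a_degradation", ["INK4A"], [], "d_ink4a"),
        ma("cyclind_degradation_ink4a", ["INK4A", "CyclinD"], ["INK4A"], "d_cd_ink4a"),
        # RAS-ERK cascade
        ma("ras_activation", ["RAGE_a", "RAS"], ["RAGE_a", "RAS_a"], "k_ras_act"),
        ma("ras_deactivation", ["RAS_a"], ["RAS"], "d_RAS"),
        ma("raf_activation", ["RAS_a", "RAF"], ["RAS_a", "RAF_a"], "k_raf_act"),
        ma("raf_deactivation", ["RAF_a"], ["RAF"], "k_raf_deact"),
        ma("mek_phosphorylation", ["RAF_a", "MEK"], ["RAF_a", "MEK_p"], "k_mek_act"),
        ma("mek_dephosphorylation", ["MEK_p"], ["MEK"], "k_mek_deact"),
        ma("erk_phosphorylation", ["MEK_p", "ERK"], ["MEK_p", "ERK_p"], "k_erk_act"),
        ma("erk_dephosphorylation", ["ERK_p"], ["ERK"], "k_erk_deact"),
        # CyclinD / Myc
        hill("cyclind_synthesis", "CyclinD", "cd_syn", "ERK_p"),
        ma("cyclind_degradation", ["CyclinD"], [], "d_cd"),
        hill("myc_synthesis", "Myc", "myc_syn", "ERK_p"),
        ma("myc_degradation", ["Myc"], [], "d_myc"),
        # Rb / E2F / RE / CyclinE
        ma("e2f_release_cyclind", ["CyclinD", "RE"], ["CyclinD", "E2F"], "k_re_cd"),
        ma("e2f_release_myc", ["Myc", "RE"], ["Myc", "E2F"], "k_re_myc"),
        ma("e2f_release_cycline", ["CyclinE", "RE"], ["CyclinE", "E2F"], "k_re_ce"),
        ma("re_formation", ["Rb", "E2F"], ["RE"], "k_re_bind"),
        ma("rb_synthesis", [], ["Rb"], "k_rb_syn"),
        ma("rb_degradation", ["Rb"], [], "d_rb"),
        ma("rb_removal_cyclind", ["CyclinD", "Rb"], ["CyclinD"], "k_rb_cd"),
        ma("rb_removal_cycline", ["CyclinE", "Rb"], ["CyclinE"], "k_rb_ce"),
        hill("e2f_synthesis", "E2F", "e2f_syn", "E2F"),
        ma("e2f_degradation", ["E2F"], [], "d_e2f"),
        hill("cycline_synthesis", "CyclinE", "ce_syn", "E2F"),
        ma("cycline_degradation", ["CyclinE"], [], "d_ce"),
    ]

    species = _species(hmgb1_init)
    init = {s.name: s.initial_count for s in species}
    conservation = tuple(
        ConservationRelation((a, b), init[a] + init[b]) for a, b in _CONSERVED_PAIRS
    )
    return ReactionNetwork(tuple(species), tuple(rxns), conservation, params)
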