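"""Frozen fragment grammar for the synthetic chemical library generator.

The generator builds molecules as scaffold + up to two substituents.  The
scaffold list and substituent list below are versioned constants, selected
(not sampled) so that the similarity structure the pipeline relies on is
achievable by construction:

* members built on the same scaffold can form clusters whose pairwise ECFP4
  Tanimoto coefficient (Tc) is >= 0.5 (within the 350-500 Da / cLogP 3-5
  property window), and
* members built on different scaffolds stay below Tc 0.36 of each other —
  the novelty cutoff used against known cannabinoid-receptor ligands — with
  an empirical margin (observed cross-scaffold maximum <= 0.34).

``REFERENCE_SCAFFOLDS`` play the role of the "known ligand" chemotype pool
(aminoalkylindole-, biphenyl-resorcinol-, arylpyrazole- and eicosanoid-like
cores); molecules derived from them are the planted known-like fraction that
a novelty filter at Tc >= 0.36 must remove.

Changing any list below changes planted ground truth everywhere; bump
``GRAMMAR_VERSION`` if you do.
"""

from __future__ import annotations

GRAMMAR_VERSION = "1.0"

#: aromatic-position substituents; "" means unsubstituted (bare ring H)
SUBSTITUENTS: tuple[str, ...] = (
    "", "C", "CC", "CCC", "C(C)C", "C1CC1", "F", "Cl", "Br", "CF",
    "C(F)F", "C(F)(F)F", "O", "OC", "OCC", "OC(F)F", "N", "NC", "N(C)C",
    "C#N", "C=C", "C(=O)C", "C(=O)OC", "C(=O)N", "C(=O)NC", "S(C)(=O)=O",
    "SC", "CO", "CCO", "OC(C)C", "CC(C)C", "CCF", "C(C)O", "OCC(F)(F)F",
    "C#C", "NCC", "C(=O)O", "CCl", "CC#N", "OCF",
)

#: novel chemotype scaffolds, one per planted cluster, ordered by the number
#: of in-window mutually-similar members each can supply (largest first)
NOVEL_SCAFFOLDS: dict[str, str] = {
    "furo_pyridine":   "Cc1occ2c(=O)n(C3CCN(C(C)=O)CC3)c(-c3cc({R1})ccc3{R2})nc12",
    "indazole_tfm":    "FC(F)(F)c1nn(-c2ccc(OC)c({R1})c2)c2cc(S(C)(=O)=O)c({R2})cc12",
    "imidazo_thiaz":   "Fc1ccc(-c2nc3sc({R1})c(C)n3c2CN2CCOC(C)C2{R2})cc1",
    "pyridyl_oxaz":    "CC(c1nc(-c2ccc({R1})nc2{R2})no1)N1CCc2sccc2C1=O",
    "quinoline_amide": "O=C(NC1CCCC1c1ccco1)c1ccc2nc({R1})ccc2c1{R2}",
    "pyrrolo_pyraz":   "Cc1nn(C2CCOC2)c2cc(C(=O)N3CCc4cc({R1})c({R2})cc4C3)cnc12",
    "pyrazolo_sulf":   "CCc1nn2cc({R1})cc(S(=O)(=O)N3CCOC(C)C3)c2c1-c1ccc(F)c({R2})c1",
    "cyclohex_oxad":   "CC1(c2nnc(-c3cc({R1})c4c(c3{R2})OCCO4)o2)CCCC1NC(C)=O",
    "gem_difluoro":    "O=C(Nc1ccc2c(c1{R1})CCC(F)(F)C2)c1cc(-c2ccco2)nn1CC({R2})F",
    "naphtho_fur":     "Cc1cc2ccc3c(c2o1)CCN(C(=O)C1(C#N)CC1)C3c1ccc({R1})c({R2})c1",
    "oxetane_sulfa":   "O=S(=O)(NC1(c2cc({R1})ccc2OC(F)F)COC1)c1ccc2c(c1)CC({R2})C2",
    "cyclobutyl_ind":  "O=C(NC1(c2ccccn2)CCC1)c1cn(C2CCC2)c2cc({R1})c({R2})cc12",
    "phenoxy_quin":    "Clc1cc2nccc(Oc3ccc({R1})cc3{R2})c2cc1C1CCNC1",
    "benzyl_pip_bz":   "O=C(c1noc(C2CC2)n1)N1CCC(Cc2cc({R1})c(F)c({R2})c2)C1",
    "indane_pz":       "O=S(=O)(N1CCN(C)C(C)C1)c1ccc2c(c1)C({R1})CC2c1nccc({R2})n1",
    "sultam_aryl":     "O=S1(=O)CCC(c2cc({R1})cc(C(=O)NC3COC3)c2{R2})N1Cc1ccsc1",
    "thieno_pyrim":    "Cc1sc2ncnc(N3CCC(c4ccc({R1})c(F)c4{R2})CC3)c2c1C",
}

#: "known ligand"-like scaffolds used for the planted known-like fraction
REFERENCE_SCAFFOLDS: dict[str, str] = {
    "ref_pyraz_hydr": "Cc1nn(-c2ccc(Cl)cc2)c(-c2ccc({R1})cc2{R2})c1C(=O)NN1CCCC1",
    "ref_aminoalkyl": "COc1ccc2c(c1)c(C(=O)c1ccc({R1})cc1{R2})cn2CCN1CCOCC1",
    "ref_eicosanoid": "CCCCC(C)(C)c1ccc(C2CCC(O)CC2)c(O{R1})c1{R2}",
    "ref_biphen_cb":  "CCCCCc1cc(OC)c(-c2ccc({R1})c(C(=O)N3CCCC3)c2{R2})c(OC)c1",
}


def instantiate(scaffold: str, r1: str, r2: str = "") -> str:
    """Substitute the {R1}/{R2} sites of a scaffold template.

    An empty substituent removes the whole parenthesized site when the
    marker sits alone inside parentheses (an unsubstituted aromatic carbon);
    bare markers are simply dropped.
    """
    smi = scaffold
    for marker, sub in (("{R1}", r1), ("{R2}", r2)):
        if sub == "":
            smi = smi.replace(f"({marker})", "").replace(marker, "")
        else:
            smi = smi.replace(marker, sub)
    return smi
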