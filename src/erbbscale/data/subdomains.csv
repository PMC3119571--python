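kinase,subdomain,start,end,note
EGFR,JM,645,671,"juxtamembrane segment preceding the kinase domain"
EGFR,N-lobe,672,767,"beta-strand-rich N lobe; ends at the gatekeeper/hinge (T766/Q767)"
EGFR,PL,695,700,"glycine-rich nucleotide-binding P-loop (GxGxxG)"
EGFR,aC,729,744,"alphaC helix; E738 is the coordinating glutamate, deletion mutants start near 723"
EGFR,aC-b4,741,748,"alphaC-beta4 loop span homologous to the ErbB2 hydrophobic patch"
EGFR,HC,745,760,"hydrophobic-core residues on the alphaC face"
EGFR,HC,834,838,"hydrophobic-core residues on the A-loop (L834, L837)"
EGFR,C-loop,806,818,"catalytic loop around the HRD motif (H811 R812 D813)"
EGFR,AL,831,852,"activation loop: DFG starts at D831, ~20 residues, contains Y845"
EGFR,AD1,679,684,"asymmetric-dimer interface, N-lobe patch around L680/I682"
EGFR,AD1,734,738,"asymmetric-dimer interface, alphaC patch around L736"
EGFR,AD1,756,764,"asymmetric-dimer interface, N-lobe patch around L758/V762"
EGFR,AD1,915,930,"asymmetric-dimer interface, activator C-lobe patch (I917-M928)"
EGFR,C-lobe,768,955,"helical C lobe of the kinase domain"
EGFR,CT,956,1186,"C-terminal tail; contains the docking tyrosines Y1068 and Y1173"
ErbB2,JM,677,703,"homolog of the EGFR juxtamembrane segment at +32 offset"
ErbB2,N-lobe,704,799,""
ErbB2,PL,727,732,""
ErbB2,aC,761,776,"alphaC helix; E770 is the coordinating glutamate"
ErbB2,aC-b4,773,782,"uniquely hydrophobic alphaC-beta4 loop (V773 M774 G776 V777 G778 V782); HSP90 binding region"
ErbB2,C-loop,838,850,"catalytic loop around H843 R844 D845"
ErbB2,AL,863,884,"activation loop: DFG starts at D863, contains Y877"
ErbB2,C-lobe,800,987,""
ErbB2,CT,988,1255,""
ErbB3,JM,647,673,"homolog of the EGFR juxtamembrane segment at +2 offset"
ErbB3,N-lobe,674,769,""
ErbB3,PL,697,702,""
ErbB3,aC,731,746,"truncated alphaC helix of the pseudokinase"
ErbB3,C-loop,808,820,"loop around H813 R814 N815 (catalytic base missing in ErbB3)"
ErbB3,AL,833,854,"activation loop: DFG starts at D833"
ErbB3,C-lobe,770,957,""
ErbB3,CT,958,1342,""
ErbB4,JM,650,676,"homolog of the EGFR juxtamembrane segment at +5 offset"
ErbB4,N-lobe,677,772,""
ErbB4,PL,700,705,""
ErbB4,aC,734,749,"alphaC helix; E743 is the coordinating glutamate"
ErbB4,aC-b4,746,753,"alphaC-beta4 loop span at +5 offset"
ErbB4,HC,750,765,"hydrophobic-core residues on the alphaC face"
ErbB4,HC,839,843,"hydrophobic-core residues on the A-loop"
ErbB4,C-loop,811,823,"catalytic loop around H816 R817 D818"
ErbB4,AL,836,857,"activation loop: DFG starts at D836, contains Y850"
ErbB4,C-lobe,773,960,""
ErbB4,CT,961,1308,""
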