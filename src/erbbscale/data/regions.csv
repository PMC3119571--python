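kinase,region,residues,provisional,note
EGFR,R-spine,742;753;811;832,False,"M742 L753 H811 F832; anchored by D872 in the alphaF helix (anchor not part of the spine set)"
EGFR,C-spine,702;719;774;819;820;821;879;883,False,"V702 A719 L774 V819 L820 V821 T879 L883; supports the adenine ring of ATP"
EGFR,dimer-interface-N,680;682;736;758;762,False,"L680 I682 L736 L758 V762; N-lobe face of the receiver kinase in the asymmetric dimer"
EGFR,dimer-interface-C,917;920;921;924;928,False,"I917 Y920 M921 V924 M928; C-lobe face of the activator kinase"
EGFR,hydrophobic-core,745;747;752;756;760;834;837,True,"provisional: hydrophobic cluster between the alphaC helix and the N-terminal A-loop (contains L834 and L837, whose clinical mutations disrupt the core); the source describes but does not enumerate this set"
EGFR,aC-b4,741;742;743;744;745;746;747;748,True,"provisional: eight-residue alphaC-beta4 span homologous to the ErbB2 hydrophobic patch"
ErbB2,aC-b4,773;774;776;777;778;782;861;862;864;866;869,False,"V773 M774 G776 V777 G778 V782 in the alphaC-beta4 loop plus the interacting A-loop patch I861 T862 F864 L866 L869"
ErbB2,R-spine,774;785;843;864,True,"provisional: homologs of the EGFR R-spine at +32 offset (M774 L785 H843 F864)"
ErbB2,C-spine,734;751;806;851;852;853;911;915,True,"provisional: homologs of the EGFR C-spine at +32 offset"
ErbB4,R-spine,747;758;816;837,True,"provisional: homologs of the EGFR R-spine at +5 offset (M747 L758 H816 F837)"
ErbB4,C-spine,707;724;779;824;825;826;884;888,True,"provisional: homologs of the EGFR C-spine at +5 offset"
ErbB4,hydrophobic-core,750;752;757;761;765;839;842,True,"provisional: homologs of the EGFR hydrophobic core at +5 offset"
ErbB3,R-spine,744;755;813;834,True,"provisional: homologs of the EGFR R-spine at +2 offset; includes segments of the truncated alphaC helix"
ErbB3,C-spine,704;721;776;821;822;823;881;885,True,"provisional: homologs of the EGFR C-spine at +2 offset"
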