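gene,subdomain,tumor_type,effect,description,aliases,citations
EGFR,HC,lung,activating,L834R,L858R (alternate numbering),b31;b32;b33
EGFR,aC,lung,activating,del 723-729 ins S,del L723-P729 ins S|del 728-729insS,b30;b31;b33
EGFR,aC,lung,resistance,T766M,T790M (alternate numbering),b127;b128;b129
EGFR,HC,lung,resistance,L834R/T766M,L858R/T790M (alternate numbering),b128;b157;b158
EGFR,AD1,lung,activating,E685S,E685G,b30;b49
EGFR,PL,lung,activating,G695S,,b30;b31
EGFR,aC,lung,activating,S744I,,b30;b31
EGFR,HC,lung,activating,L837Q,,b30;b49
EGFR,aC-b4,lung,activating,,,b50;b51
EGFR,aC-b4,skin,activating,,,b52
EGFR,aC,breast,activating,,,b53
EGFR,aC,prostate,activating,,,b54
EGFR,aC,kidney,activating,,,b95;b96
EGFR,aC,thyroid,activating,,,b97
EGFR,AL,thyroid,activating,,,b97
EGFR,AD1,thyroid,activating,,,b98
ErbB2,aC-b4,lung,activating,G776^YVMA^,G776YVMA,b56;b57;b58
ErbB2,aC,lung,activating,,,b55
ErbB2,aC-b4,colon,activating,,,b55
ErbB2,aC-b4,breast,activating,,,b55
ErbB2,aC,breast,activating,,,b59
ErbB2,aC-b4,ovary,activating,,,b99;b100;b101
ErbB4,AL,colon,activating,,,b60
ErbB4,AL,skin,activating,E836K; E872K,,b61
ErbB4,C-lobe,skin,activating,G936R,,b61
ErbB4,AL,breast,activating,,,b60
ErbB4,aC,gastrointestinal,activating,,,b60
ErbB4,PL,lung,loss-of-function,G802dup,G802dup*,b94
ErbB4,AL,lung,loss-of-function,D861Y,D861Y*,b94
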