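structure_id,enzyme_form,space_group,molar_ratio,chain,partner,conformation,occupancy
WT-6(P/S)-2FA,WT,P212121,0.14,A,D,closed,0.7
WT-6(P/S)-2FA,WT,P212121,0.14,F,C,closed,0.7
WT-6(P/S)-2FA,WT,P212121,0.14,D,A,open,
WT-6(P/S)-2FA,WT,P212121,0.14,C,F,open,
WT-6(P/S)-2FA,WT,P212121,0.14,B,E,open,
WT-6(P/S)-2FA,WT,P212121,0.14,E,B,open,
WT-6(P/S)-6FA,WT,P6122,0.57,A,D,closed,0.8
WT-6(P/S)-6FA,WT,P6122,0.57,D,A,open,0.5
WT-6(P/S)-6FA,WT,P6122,0.57,B,B',open,0.4
DM-6(P/S)-2FA,DM,P212121,0.4,A,D,closed,
DM-6(P/S)-2FA,DM,P212121,0.4,F,C,closed,
DM-6(P/S)-2FA,DM,P212121,0.4,D,A,open,0.7
DM-6(P/S)-2FA,DM,P212121,0.4,C,F,open,0.7
DM-6(P/S)-2FA,DM,P212121,0.4,B,E,open,
DM-6(P/S)-2FA,DM,P212121,0.4,E,B,open,
DM-6(P/S)-4FA,DM,P212121,0.6,A,D,closed,0.6
DM-6(P/S)-4FA,DM,P212121,0.6,F,C,closed,0.6
DM-6(P/S)-4FA,DM,P212121,0.6,D,A,open,0.6
DM-6(P/S)-4FA,DM,P212121,0.6,C,F,open,0.6
DM-6(P/S)-4FA,DM,P212121,0.6,B,E,open,
DM-6(P/S)-4FA,DM,P212121,0.6,E,B,open,
DM-6(P/S)-6FA,DM,P6122,1.2,A,D,closed,0.7
DM-6(P/S)-6FA,DM,P6122,1.2,D,A,open,0.5
DM-6(P/S)-6FA,DM,P6122,1.2,B,B',open,0.6
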