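peptide_id,sequence,Ki_pM,Ki_SE_pM,note
bivalirudin,FPRPGGGGNGDFEEIPEEYL,1780,152,N-terminal residue is D-Phe
BV001,PGGGGNGDFEEIPEEYL,,,no inhibition; activation above 1 uM
variegin,SDQGDVAEPKMHKTAPPFDFEAIPEEYLDDES,277,56,
avathrin,SGGHQTAVPKISKQGLGGDFEEIPSDEIIE,624,86,
DAA34688.1_repeat_1,SDEAVRAIPKMYSTAPPGDFETIPDDAIEEREMKAR,43.2,8.0,
DAA34688.1_repeat_1B,SDEAVRAIPKMYSTAPPGDFETIPDDAIEER,20.5,4.7,
DAA34688.1_repeat_1C,SDEAVRAIPKMYSTAPPGDFETIPDDAIEE,6.5,1.3,
ultravariegin,SDEAVRAIPKMYSTAPPGDFEEIPDDAIEE,4.0,0.5,
UV003,SDQGDVAIPKMYSTAPPGDFEEIPDDAIEE,4.2,1.0,
UV004,SDEAVRAEPKMHKTAPPGDFEEIPDDAIEE,4.6,0.4,
UV005,SDEAVRAIPKMYSTAPPGDFEEIPEEYLDDES,16.0,0.3,
UV012,SDEAVRAIPKMYSTAPPGDFEEIPDDEIEE,23.0,8.1,
UV013,SDEAVRAIPKMYSQAPPGDFEEIPDDAIEE,4.5,1.6,
UV011,MYSTAPPGDFEEIPDDAIEE,1660,759,thrombin-cleavage product; non-competitive Ki = IC50
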