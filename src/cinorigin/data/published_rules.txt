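# Published 23-rule decision list for CGE/dMGE/vMGE region-of-origin calls
# on the GSE109796 subpallium single-cell dataset (RPKM thresholds).
# 22 explicit rules: 1-12 CGE, 13-22 vMGE; dMGE is the default class.
(NKX2-1 <= 3.6524) and (MT-TM >= 1.4699) and (MEIS2 >= 0.7558) and (H3F3B >= 2019.223223) => CGE
(FOXP2 >= 0.0047) and (NKX2-1 <= 5.5415) and (TMSB10 <= 76.7268) and (NR2F1 >= 25.2511) => CGE
(NKX2-1 <= 12.9594) and (RPS20 <= 17.1104) and (SLC7A11 >= 0.0538) and (PID1 >= 0.4191) and (LHX8 <= 0.0839) => CGE
(NR2F2 >= 0.2374) and (LHX6 <= 0.3856) and (5730494M16RIK >= 14.4383) and (LHX8 <= 7.0592) => CGE
(FOXP2 >= 0.1294) and (EPHA5 >= 25.8453) and (RPS9 <= 159.5439) and (DCX >= 49.7284) => CGE
(NR2F2 >= 2.2717) and (EPHA5 >= 3.4019) and (LHX8 <= 0.0) and (MEIS2 >= 18.9392) and (NCAPH <= 2.4094) => CGE
(ENC1 <= 1.8862) and (NKX2-1 <= 12.0905) and (STX7 >= 0.3228) and (CALM1 <= 546.2493) and (SOX6 <= 2.819) => CGE
(GM6180 >= 36.7994) and (FOXP2 >= 3.5745) and (GM13340 >= 34.469118) => CGE
(EPHA5 >= 0.1196) and (LHX8 <= 0.1496) and (GM15266 <= 19.2334) and (GM1821 <= 89.839694) and (CALM1 <= 744.1502) => CGE
(BIRC6 <= 0.0) and (NKX2-1 <= 10.7393) and (CRIP2 >= 400.8077) and (ZFP238 >= 6.181) and (GM10039 >= 12.3788) => CGE
(ARRDC3 >= 368.6154) and (PTPRS <= 24.5126) and (ZFP238 <= 70.9705) => CGE
(ZFP503 >= 0.1111) and (MAP4K4 <= 7.0016) => CGE
(LHX8 >= 1.4487) and (ZIC1 >= 0.0111) => vMGE
(LHX8 >= 0.3736) and (NR2F1 <= 9.4921) and (ZSWIM5 <= 0.0334) => vMGE
(NR2F1 <= 15.6811) and (CD24A >= 2.7069) and (BASP1 <= 66.0865) and (PKIA <= 1.8492) => vMGE
(PAK3 <= 0.7899) and (RPS18 >= 4.9001) and (PID1 >= 1.2578) => vMGE
(YWHAZ >= 1.8915) and (SEPT11 <= 7.8189) and (GM13604 <= 0.2081) and (H2AFV >= 1305.9678) => vMGE
(PAK3 <= 0.0474) and (CFL1 >= 31.1042) and (GTF2A1 <= 20.8911) and (LHX6 <= 5.6025) => vMGE
(GM15266 <= 63.0475) and (MT-RNR2 >= 9387.3828) => vMGE
(CITED2 <= 35.2427) and (GM10718 <= 1.0898) and (2610017I09RIK <= 2442.7505) and (GSK3B <= 1.5164) => vMGE
(UBE2QL1 >= 1.5601) and (3110003A17RIK >= 20.2789) and (RTN1 <= 4.7837) => vMGE
(GM3511 >= 22.986) and (PTMA >= 2.2359) and (LHX6 <= 47.9178) => vMGE
others => dMGE
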