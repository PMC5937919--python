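# Derivative compositions of the measured [M - CH3]+ ions.
#
# Ethoxime-trimethylsilyl derivatization of sugar phosphates: the carbonyl
# becomes an ethoxime (2 C), every free hydroxyl including the two phosphate
# OH groups a TMS group (3 C, 1 Si), and the measured ion loses one methyl
# (1 C) from a TMS group.  Group counts per metabolite follow from standard
# structures; Rl5P (5 TMS + 1 EtOx -> 16 extra C, 5 Si) is the documented
# reference case.
G6P:
  backbone_carbons: 6
  neutral_loss_carbons: 1
  groups:
    - {name: EtOx, carbons: 2, silicons: 0, count: 1}
    - {name: TMS, carbons: 3, silicons: 1, count: 6}
F6P:
  backbone_carbons: 6
  neutral_loss_carbons: 1
  groups:
    - {name: EtOx, carbons: 2, silicons: 0, count: 1}
    - {name: TMS, carbons: 3, silicons: 1, count: 6}
GAP:
  backbone_carbons: 3
  neutral_loss_carbons: 1
  groups:
    - {name: EtOx, carbons: 2, silicons: 0, count: 1}
    - {name: TMS, carbons: 3, silicons: 1, count: 3}
DHAP:
  backbone_carbons: 3
  neutral_loss_carbons: 1
  groups:
    - {name: EtOx, carbons: 2, silicons: 0, count: 1}
    - {name: TMS, carbons: 3, silicons: 1, count: 3}
E4P:
  backbone_carbons: 4
  neutral_loss_carbons: 1
  groups:
    - {name: EtOx, carbons: 2, silicons: 0, count: 1}
    - {name: TMS, carbons: 3, silicons: 1, count: 4}
RUL5P:
  backbone_carbons: 5
  neutral_loss_carbons: 1
  groups:
    - {name: EtOx, carbons: 2, silicons: 0, count: 1}
    - {name: TMS, carbons: 3, silicons: 1, count: 5}
RIB5P:
  backbone_carbons: 5
  neutral_loss_carbons: 1
  groups:
    - {name: EtOx, carbons: 2, silicons: 0, count: 1}
    - {name: TMS, carbons: 3, silicons: 1, count: 5}
SED7P:
  backbone_carbons: 7
  neutral_loss_carbons: 1
  groups:
    - {name: EtOx, carbons: 2, silicons: 0, count: 1}
    - {name: TMS, carbons: 3, silicons: 1, count: 7}
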