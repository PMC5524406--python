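# Study-design template: population codes, language-group labels,
# per-population sample sizes for the three marker systems, and the
# per-population Y-haplogroup composition (percent, one decimal).
populations:
- code: KM1
  name: Khon Muang 1
  group: KM
  n_hvri: 50
  n_ystr: 21
  n_ysnp: 21
  haplogroup_percent:
    N-M231: 9.5
    O-P203: 4.8
    O-PK4: 19.1
    O-M111: 23.8
    O-M324: 14.3
    O-M7: 4.7
    O-M117: 23.8
- code: KM2
  name: Khon Muang 2
  group: KM
  n_hvri: 41
  n_ystr: 16
  n_ysnp: 16
  haplogroup_percent:
    C-M217: 6.2
    N-M231: 12.5
    O-PK4: 31.3
    O-M111: 25.0
    O-M117: 25.0
- code: KM3
  name: Khon Muang 3
  group: KM
  n_hvri: 36
  n_ystr: 15
  n_ysnp: 15
  haplogroup_percent:
    C-M130: 6.7
    O-P203: 6.7
    O-PK4: 20.0
    O-M111: 20.0
    O-M324: 13.3
    O-M7: 13.3
    O-M117: 20.0
- code: KM4
  name: Khon Muang 4
  group: KM
  n_hvri: 52
  n_ystr: 29
  n_ysnp: 29
  haplogroup_percent:
    C-M217: 3.5
    E-P173: 3.5
    H-M52: 3.5
    N-M231: 10.3
    O-PK4: 27.6
    O-M111: 13.8
    O-M324: 13.8
    O-M7: 6.8
    O-M117: 17.2
- code: KM5
  name: Khon Muang 5
  group: KM
  n_hvri: 43
  n_ystr: 20
  n_ysnp: 21
  haplogroup_percent:
    C-M217: 4.8
    D-M15: 4.8
    O-P203: 14.3
    O-PK4: 23.8
    O-M111: 19.0
    O-M324: 14.3
    O-M7: 9.5
    O-M117: 9.5
- code: KM6
  name: Khon Muang 6
  group: KM
  n_hvri: 45
  n_ystr: 22
  n_ysnp: 22
  haplogroup_percent:
    C-M130: 4.6
    C-M356: 4.6
    C-M217: 4.6
    D-M15: 4.6
    J-M172: 4.6
    O-PK4: 27.0
    O-M111: 4.6
    O-M122: 4.6
    O-M324: 9.0
    O-M7: 4.6
    O-M117: 18.2
    R-M173: 9.0
- code: KM7
  name: Khon Muang 7
  group: KM
  n_hvri: 46
  n_ystr: 23
  n_ysnp: 23
  haplogroup_percent:
    D-M15: 4.4
    O-PK4: 8.7
    O-M111: 30.3
    O-M324: 4.4
    O-M7: 8.7
    O-M117: 43.5
- code: KM8
  name: Khon Muang 8
  group: KM
  n_hvri: 45
  n_ystr: 22
  n_ysnp: 22
  haplogroup_percent:
    C-M130: 4.6
    C-M217: 9.0
    L-M76: 9.0
    N-M231: 4.6
    O-P203: 4.6
    O-M50: 9.0
    O-PK4: 18.2
    O-M111: 13.6
    O-M324: 4.6
    O-M7: 4.6
    O-M117: 18.2
- code: KM9
  name: Khon Muang 9
  group: KM
  n_hvri: 45
  n_ystr: 22
  n_ysnp: 22
  haplogroup_percent:
    D-M15: 4.6
    K-P128: 4.6
    N-M231: 4.6
    O-PK4: 22.7
    O-M111: 22.7
    O-M7: 9.0
    O-M117: 31.8
- code: KM10
  name: Khon Muang 10
  group: KM
  n_hvri: 30
  n_ystr: 14
  n_ysnp: 14
  haplogroup_percent:
    C-M130: 7.1
    O-PK4: 35.7
    O-M111: 14.3
    O-M7: 28.6
    O-M117: 14.3
- code: MO
  name: Mon
  group: MK
  n_hvri: 41
  n_ystr: 15
  n_ysnp: 18
  haplogroup_percent:
    J-M172: 5.6
    O-P203: 5.6
    O-PK4: 33.2
    O-M324: 16.7
    O-M117: 22.2
    R-P249: 16.7
- code: LW1
  name: Lawa 1
  group: MK
  n_hvri: 46
  n_ystr: 25
  n_ysnp: 25
  haplogroup_percent:
    D-M15: 4.0
    N-M231: 4.0
    O-PK4: 72.0
    O-M117: 20.0
- code: LW2
  name: Lawa 2
  group: MK
  n_hvri: 50
  n_ystr: 25
  n_ysnp: 25
  haplogroup_percent:
    N-M231: 56.0
    O-PK4: 16.0
    O-M111: 4.0
    O-M324: 24.0
- code: KH
  name: Khuen
  group: TK
  n_hvri: 60
  n_ystr: 29
  n_ysnp: 24
  haplogroup_percent:
    D-M15: 8.3
    N-M231: 16.7
    O-P203: 4.2
    O-PK4: 25.0
    O-M111: 25.0
    O-M134: 4.1
    O-M117: 16.7
- code: LU1
  name: Lue 1
  group: TK
  n_hvri: 51
  n_ystr: 25
  n_ysnp: 24
  haplogroup_percent:
    C-M217: 8.3
    D-M15: 4.2
    NO-P195: 4.2
    O-P203: 12.4
    O-PK4: 25.0
    O-M111: 16.7
    O-M122: 4.2
    O-M7: 8.3
    O-M117: 16.7
- code: LU2
  name: Lue 2
  group: TK
  n_hvri: 44
  n_ystr: 21
  n_ysnp: 22
  haplogroup_percent:
    O-P203: 9.1
    O-M50: 13.6
    O-PK4: 31.8
    O-M111: 27.3
    O-M7: 9.1
    O-M117: 9.1
- code: LU3
  name: Lue 3
  group: TK
  n_hvri: 50
  n_ystr: 26
  n_ysnp: 26
  haplogroup_percent:
    NO-P195: 4.0
    O-P203: 4.0
    O-PK4: 23.0
    O-M111: 23.0
    O-M324: 11.5
    O-M7: 7.7
    O-M117: 26.8
- code: LU4
  name: Lue 4
  group: TK
  n_hvri: 46
  n_ystr: 24
  n_ysnp: 19
  haplogroup_percent:
    N-M231: 5.3
    O-PK4: 15.8
    O-M111: 63.2
    O-M117: 15.8
- code: YU1
  name: Yuan 1
  group: TK
  n_hvri: 39
  n_ystr: 20
  n_ysnp: 19
  haplogroup_percent:
    C-M217: 5.3
    O-PK4: 42.1
    O-M111: 21.0
    O-M134: 10.5
    O-M117: 15.8
    R-M173: 5.3
- code: YU2
  name: Yuan 2
  group: TK
  n_hvri: 50
  n_ystr: 25
  n_ysnp: 23
  haplogroup_percent:
    C-M217: 4.4
    N-M231: 4.4
    O-PK4: 26.1
    O-M111: 30.4
    O-M122: 4.3
    O-M7: 8.7
    O-M117: 21.7
- code: YU3
  name: Yuan 3
  group: TK
  n_hvri: 50
  n_ystr: 26
  n_ysnp: 24
  haplogroup_percent:
    C-M130: 4.2
    C-M217: 12.5
    D-M15: 4.2
    N-M231: 16.6
    O-P203: 4.2
    O-PK4: 8.3
    O-M111: 20.8
    O-M122: 16.6
    O-M134: 4.2
    O-M117: 4.2
    R-M173: 4.2
- code: YU4
  name: Yuan 4
  group: TK
  n_hvri: 44
  n_ystr: 21
  n_ysnp: 19
  haplogroup_percent:
    H-M52: 5.3
    N-M231: 5.3
    O-P203: 10.5
    O-PK4: 15.8
    O-M111: 15.8
    O-M7: 15.8
    O-M117: 31.5
- code: YO
  name: Yong
  group: TK
  n_hvri: 62
  n_ystr: 31
  n_ysnp: 26
  haplogroup_percent:
    D-M15: 3.9
    N-M231: 3.9
    O-P203: 7.7
    O-M50: 3.9
    O-PK4: 7.7
    O-M111: 38.4
    O-M324: 15.4
    O-M7: 7.7
    O-M117: 11.4
- code: SH
  name: Shan
  group: TK
  n_hvri: 43
  n_ystr: 19
  n_ysnp: 20
  haplogroup_percent:
    CF-P143: 5.0
    N-M231: 5.0
    O-P203: 5.0
    O-PK4: 30.0
    O-M111: 15.0
    O-M7: 5.0
    O-M117: 35.0
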