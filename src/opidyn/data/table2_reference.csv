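outcome,decade,factor,cumulative,theta
heroin,1,1.25,-14451,-1.01
heroin,2,1.25,-21935,-1.38
heroin,3,1.25,-26187,-1.49
heroin,1,1.5,-26885,-1.88
heroin,2,1.5,-39516,-2.48
heroin,3,1.5,-46552,-2.66
heroin,1,1.75,-37820,-2.65
heroin,2,1.75,-53982,-3.39
heroin,3,1.75,-62906,-3.59
heroin,1,0.75,16949,1.18
heroin,2,0.75,27928,1.75
heroin,3,0.75,34696,1.98
heroin,1,0.5,37020,2.58
heroin,2,0.5,64227,4.03
heroin,3,0.5,82173,4.69
heroin,1,0.25,61029,4.25
heroin,2,0.25,112586,7.06
heroin,3,0.25,149781,8.54
deaths,1,1.25,-9605,-0.64
deaths,2,1.25,-17104,-1.02
deaths,3,1.25,-21046,-1.15
deaths,1,1.5,-17921,-1.19
deaths,2,1.5,-30931,-1.85
deaths,3,1.5,-37493,-2.04
deaths,1,1.75,-25218,-1.68
deaths,2,1.75,-42313,-2.54
deaths,3,1.75,-50658,-2.76
deaths,1,0.75,11200,0.74
deaths,2,0.75,21588,1.29
deaths,3,0.75,27739,1.51
deaths,1,0.5,24368,1.62
deaths,2,0.5,49343,2.95
deaths,3,0.5,65412,3.56
deaths,1,0.25,40000,2.65
deaths,2,0.25,85875,5.14
deaths,3,0.25,118560,6.45
abstinence,1,1.25,113939,1.26
abstinence,2,1.25,78494,0.77
abstinence,3,1.25,70298,0.62
abstinence,1,1.5,210081,2.33
abstinence,2,1.5,137081,1.34
abstinence,3,1.5,122070,1.08
abstinence,1,1.75,294956,3.27
abstinence,2,1.75,184774,1.81
abstinence,3,1.75,164843,1.46
abstinence,1,0.75,-136191,-1.50
abstinence,2,0.75,-107179,-1.05
abstinence,3,0.75,-98697,-0.88
abstinence,1,0.5,-301044,-3.31
abstinence,2,0.5,-257878,-2.52
abstinence,3,0.5,-244509,-2.17
abstinence,1,0.25,-502722,-5.52
abstinence,2,0.25,-475200,-4.65
abstinence,3,0.25,-470733,-4.18
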