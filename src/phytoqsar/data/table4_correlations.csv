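parameter,g_bind,homo,lumo,delta_e,ip,ea,eta,xi,chi,mu,omega
g_bind,1.00,-0.51,0.93,0.91,0.51,-0.93,0.91,-0.92,-0.90,0.90,-0.55
homo,-0.87,1.00,-0.57,-0.73,-1.00,0.57,-0.72,0.68,0.31,-0.31,0.10
lumo,0.83,-0.69,1.00,0.98,0.57,-1.00,0.98,-0.99,-0.96,0.96,-0.52
delta_e,0.88,-0.77,0.99,1.00,0.73,-0.98,1.00,-1.00,-0.88,0.88,-0.46
ip,0.87,-1.00,0.69,0.77,1.00,-0.57,0.72,-0.68,-0.31,0.31,-0.10
ea,-0.83,0.69,-1.00,-0.99,-0.57,1.00,-0.98,0.99,0.96,-0.96,0.52
eta,0.88,-0.77,0.99,1.00,0.72,-0.98,1.00,-1.00,-0.88,0.88,-0.46
xi,-0.89,0.82,-0.98,-0.99,-0.68,0.99,-1.00,1.00,0.91,-0.91,0.44
chi,-0.76,0.58,-0.99,-0.96,-0.31,0.96,-0.88,0.93,1.00,-1.00,0.57
mu,0.76,-0.58,0.99,0.96,0.31,-0.96,0.88,-0.93,-1.00,1.00,-0.57
omega,-0.86,0.74,-0.99,-0.99,-0.10,0.52,-0.46,0.99,0.97,-0.97,1.00
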